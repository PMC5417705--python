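"""Event-level flow-cytometry processing.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``cell_id, fsc, ssc, ch1_raw, ch2_raw``.  Processing appends:

* ``pass_scatter`` — kept by the FSC/SSC density gate;
* ``gfp``, ``mcherry`` — unmixed, background-subtracted fluorescence;
* ``pass_dual`` — positive in both channels (implies ``pass_scatter``);
* ``gated`` — final alias of ``pass_dual``.

Crosstalk between the GFP and mCherry detector channels is modelled as
linear mixing with unit diagonal::

    ch1_raw = gfp      + m12 * mcherry   (+ background)
    ch2_raw = m21 * gfp + mcherry        (+ background)

estimated from single-colour control strains and removed by inverting
the 2x2 matrix (standard compensation).  Backgrounds are per-channel
medians of a blank (no-fluorophore) control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CrosstalkMatrix",
    "GateSpec",
    "gate_scatter",
    "estimate_background",
    "estimate_crosstalk",
    "unmix",
    "gate_dual_positive",
    "process_events",
    "read_events_csv",
    "write_events_csv",
]

RAW_COLUMNS = ["cell_id", "fsc", "ssc", "ch1_raw", "ch2_raw"]

MIN_EVENTS_FOR_GATE = 50


@dataclass(frozen=True)
class CrosstalkMatrix:
    """2x2 spectral mixing matrix with unit diagonal.

    ``m12``: fraction of mCherry emission read by the GFP detector;
    ``m21``: fraction of GFP emission read by the mCherry detector.
    """

    m12: float
    m21: float

    def __post_init__(self) -> None:
        for v in (self.m12, self.m21):
            if not (0 <= v < 1):
                raise ValueError(f"off-diagonal crosstalk must be in [0, 1), got {v}")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("crosstalk matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[1.0, self.m12], [self.m21, 1.0]])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class GateSpec:
    """Gating parameters: ``scatter_density_quantile`` is the fraction of
    events retained by the scatter gate (densest first); positivity
    thresholds are per-channel fluorescence floors or ``"auto"`` (the 99th
    percentile of the blank control per channel)."""

    scatter_density_quantile: float = 0.95
    gfp_threshold: float | str = "auto"
    mcherry_threshold: float | str = "auto"
    scatter_grid_bins: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.scatter_density_quantile <= 1):
            raise ValueError("scatter_density_quantile must be in (0, 1]")


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing event columns {missing}")
    return df


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def _grid_density(x: np.ndarray, y: np.ndarray, bins: int) -> np.ndarray:
    """Smoothed 2-D histogram density evaluated at each event."""
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    hist = ndimage.gaussian_filter(hist, sigma=1.0)
    xi = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, bins - 1)
    yi = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, bins - 1)
    return hist[xi, yi]


def gate_scatter(events: pd.DataFrame, spec: GateSpec = GateSpec()) -> pd.DataFrame:
    """Keep the densest ``scatter_density_quantile`` fraction of events on
    the (log FSC, log SSC) plane — the reproducible analogue of drawing a
    gate around cells of regular size and shape.

    Returns a copy with a ``pass_scatter`` flag; refuses fewer than 50
    events (the density estimate is meaningless).  Degenerate constant
    scatter retains everything with a warning.
    """
    if len(events) < MIN_EVENTS_FOR_GATE:
        raise ValueError(f"scatter gate needs >= {MIN_EVENTS_FOR_GATE} events, got {len(events)}")
    out = events.copy()
    x = np.log(events["fsc"].to_numpy(float))
    y = np.log(events["ssc"].to_numpy(float))
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite scatter values (fsc/ssc must be positive)")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("constant scatter signal: retaining all events")
        out["pass_scatter"] = True
        return out
    density = _grid_density(x, y, spec.scatter_grid_bins)
    n_keep = int(round(spec.scatter_density_quantile * len(events)))
    order = np.argsort(density, kind="stable")  # ties broken by event order
    flag = np.zeros(len(events), dtype=bool)
    flag[order[len(events) - n_keep:]] = True
    out["pass_scatter"] = flag
    return out


def estimate_background(blank: pd.DataFrame) -> np.ndarray:
    """Per-channel background: median raw signal of the blank control."""
    return np.array([blank["ch1_raw"].median(), blank["ch2_raw"].median()])


def estimate_crosstalk(gfp_only: pd.DataFrame, mcherry_only: pd.DataFrame,
                       blank: pd.DataFrame, *,
                       negative_tolerance: float = 0.01) -> CrosstalkMatrix:
    """Estimate the mixing matrix from single-colour controls.

    After background subtraction, the GFP-only strain's mCherry-channel
    signal is pure bleed-through, so ``m21`` is the least-squares slope
    through the origin of ``ch2_raw`` on ``ch1_raw`` over its events
    (symmetrically for ``m12``).  Slopes below ``-negative_tolerance`` or
    at/above 1 indicate swapped controls or signal inversion and are
    refused; small negative estimates are clamped to 0.
    """
    bg = estimate_background(blank)

    def slope(df: pd.DataFrame, x_col: str, y_col: str) -> float:
        x = df[x_col].to_numpy(float) - bg[0 if x_col == "ch1_raw" else 1]
        y = df[y_col].to_numpy(float) - bg[0 if y_col == "ch1_raw" else 1]
        sxx = float(np.dot(x, x))
        if sxx == 0:
            raise ValueError("control has zero signal variance; cannot estimate crosstalk")
        s = float(np.dot(x, y)) / sxx
        if s >= 1 or s < -negative_tolerance:
            raise ValueError(
                f"crosstalk slope {s:.4f} outside [0, 1): swapped controls or inverted signal?")
        return max(s, 0.0)

    m21 = slope(gfp_only, "ch1_raw", "ch2_raw")
    m12 = slope(mcherry_only, "ch2_raw", "ch1_raw")
    return CrosstalkMatrix(m12=m12, m21=m21)


def unmix(events: pd.DataFrame, m: CrosstalkMatrix,
          blank: pd.DataFrame | None = None, *,
          background: np.ndarray | None = None,
          clip_negative: bool = False) -> pd.DataFrame:
    """Linear compensation: ``[gfp, mcherry] = M^-1 (raw - background)``.

    Negative unmixed values are measurement noise around zero and are kept
    by default so strain means stay unbiased (``clip_negative=True`` to
    floor at 0).
    """
    if background is None:
        background = estimate_background(blank) if blank is not None else np.zeros(2)
    raw = events[["ch1_raw", "ch2_raw"]].to_numpy(float) - background
    unmixed = raw @ m.inverse.T
    if clip_negative:
        unmixed = np.maximum(unmixed, 0.0)
    out = events.copy()
    out["gfp"] = unmixed[:, 0]
    out["mcherry"] = unmixed[:, 1]
    return out


def gate_dual_positive(events: pd.DataFrame, spec: GateSpec = GateSpec(),
                       blank_unmixed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Require a positive signal in both channels, removing cells that lost
    one reporter (loss of heterozygosity, typically <2% of cells).

    ``"auto"`` thresholds need ``blank_unmixed`` — the blank control passed
    through the same :func:`unmix` — and use its 99th percentile per
    channel.  Warns loudly when more than half the cells fail (suspect
    induction failure) and when one channel empties the table.
    """
    if "gfp" not in events.columns:
        raise ValueError("events must be unmixed before the dual-positivity gate")

    def threshold(setting: float | str, column: str) -> float:
        if setting == "auto":
            if blank_unmixed is None:
                raise ValueError("auto thresholds require the unmixed blank control")
            return float(np.quantile(blank_unmixed[column].to_numpy(float), 0.99))
        return float(setting)

    thr_gfp = threshold(spec.gfp_threshold, "gfp")
    thr_mch = threshold(spec.mcherry_threshold, "mcherry")
    out = events.copy()
    base = out["pass_scatter"] if "pass_scatter" in out.columns else True
    positive = (out["gfp"].to_numpy(float) > thr_gfp) & \
               (out["mcherry"].to_numpy(float) > thr_mch)
    out["pass_dual"] = np.asarray(base, dtype=bool) & positive
    out["gated"] = out["pass_dual"]
    considered = int(np.sum(np.asarray(base, dtype=bool)))
    kept = int(out["pass_dual"].sum())
    if considered and kept == 0:
        warnings.warn("dual-positivity gate removed every event: threshold above all cells?")
    elif considered and (considered - kept) / considered > 0.5:
        warnings.warn(f"dual-positivity gate removed {considered - kept}/{considered} events "
                      "(>50%): suspect induction failure")
    return out


def process_events(events: pd.DataFrame, m: CrosstalkMatrix, blank: pd.DataFrame,
                   spec: GateSpec = GateSpec()) -> pd.DataFrame:
    """Full per-strain pipeline: scatter gate, unmix, dual-positivity gate.

    The blank control is unmixed with the same matrix to supply auto
    thresholds.
    """
    gated = gate_scatter(events, spec)
    unmixed = unmix(gated, m, blank)
    blank_unmixed = unmix(blank, m, blank)
    return gate_dual_positive(unmixed, spec, blank_unmixed=blank_unmixed)
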