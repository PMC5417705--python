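"""Library-level screen: strain summaries, 3-SD outlier calls, profiles.

The screen collapses each strain's gated single-cell events to a mean,
SD and CV per channel, normalizes means so that the average of the
"normal" (profile-1) strains is 1, and calls a strain an outlier in a
channel when its normalized mean lies more than ``z_cutoff`` (default 3)
standard deviations from the library mean.

Normalization and outlier calling are circular — profile 1 is defined as
the non-outlier set, but the outlier rule needs the profile-1 mean and
SD — so both are resolved by iteration: start from the library median,
call outliers, re-anchor mean/SD on the non-outliers, repeat until the
outlier set is stable.  The iterated SD is deliberately computed over
non-outliers only; a single-pass SD is inflated by the outliers
themselves (``single_pass=True`` reproduces it for comparison).

GFP outliers are then classified on the noise-vs-mean plane:

* profile 2 — low mean, CV above the fitted CV-mean trend (silencing);
* profile 3 — low mean, CV on the trend (e.g. transcriptional
  interference);
* profile 4 — high mean (spatial clustering with co-regulated genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScreenResult",
    "summarize_strain",
    "summarize_library",
    "normalize_library",
    "call_outliers",
    "classify_profiles",
    "screen_library",
    "compare_noise",
    "read_summary_table",
]

MIN_CELLS = 200
MIN_STRAINS = 20
CHANNELS = ("gfp", "mcherry")


def summarize_strain(events: pd.DataFrame, strain_id: str = "",
                     min_cells: int = MIN_CELLS) -> pd.Series:
    """Per-strain mean, sample SD (n-1) and CV of each channel over gated
    cells.  A non-positive mean leaves the CV undefined and flags the
    strain invalid."""
    gated = events[events["gated"]] if "gated" in events.columns else events
    n = len(gated)
    rec: dict = {"strain": strain_id, "n_cells": n, "valid": n >= min_cells}
    for ch in CHANNELS:
        x = gated[ch].to_numpy(float)
        mean = float(x.mean()) if n else np.nan
        sd = float(x.std(ddof=1)) if n > 1 else np.nan
        rec[f"{ch}_mean"] = mean
        rec[f"{ch}_sd"] = sd
        if n and mean > 0:
            rec[f"{ch}_cv"] = sd / mean
        else:
            rec[f"{ch}_cv"] = np.nan
            rec["valid"] = False
    return pd.Series(rec)


def summarize_library(events_by_strain: dict[str, pd.DataFrame],
                      min_cells: int = MIN_CELLS) -> pd.DataFrame:
    rows = [summarize_strain(ev, sid, min_cells) for sid, ev in events_by_strain.items()]
    return pd.DataFrame(rows).reset_index(drop=True)


def _iterate_outliers(norm: np.ndarray, z_cutoff: float, max_iter: int,
                      single_pass: bool, zero_sd: str = "raise",
                      ) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Iterated z-scores for one channel.

    Returns (z, outlier_flags, n_iter, converged).  The reference mean/SD
    are recomputed over the current non-outlier set until that set is
    stable.  ``zero_sd`` selects whether a degenerate (constant) library
    raises or yields all-zero z-scores.
    """
    flags = np.zeros(len(norm), dtype=bool)
    z = np.zeros(len(norm))
    for it in range(1, max_iter + 1):
        ref = norm[~flags]
        m, s = float(ref.mean()), float(ref.std(ddof=1))
        if s == 0:
            if zero_sd == "tolerate":
                return np.zeros(len(norm)), flags, it, True
            raise ValueError("zero library SD: cannot standardize expression")
        z = (norm - m) / s
        new_flags = np.abs(z) > z_cutoff
        if single_pass:
            return z, new_flags, 1, True
        if np.array_equal(new_flags, flags):
            return z, flags, it, True
        flags = new_flags
    warnings.warn(f"outlier set did not stabilize in {max_iter} iterations; "
                  "reporting the last set")
    return z, flags, max_iter, False


def normalize_library(summaries: pd.DataFrame, z_cutoff: float = 3.0,
                      max_iter: int = 10, single_pass: bool = False,
                      zero_sd: str = "tolerate") -> pd.DataFrame:
    """Normalize per-channel means to the average of the non-outlier
    (profile-1) strains and attach iterated z-scores.

    Scheme: start from the library median, call |z| > cutoff outliers,
    re-anchor on the mean of non-outliers, repeat.  Adds, per channel,
    ``{ch}_norm`` and ``z_{ch}`` columns plus the ``n_iter_{ch}`` count.
    """
    if len(summaries) < MIN_STRAINS:
        raise ValueError(f"need >= {MIN_STRAINS} strains to normalize, got {len(summaries)}")
    out = summaries.copy()
    for ch in CHANNELS:
        mean = out[f"{ch}_mean"].to_numpy(float)
        if np.nanmedian(mean) <= 0:
            raise ValueError(f"non-positive library median in channel {ch}")
        norm = mean / np.nanmedian(mean)
        z, flags, n_iter, _ = _iterate_outliers(norm, z_cutoff, max_iter, single_pass,
                                                zero_sd=zero_sd)
        # anchor the scale on the non-outlier average (profile-1 average = 1)
        norm = norm / norm[~flags].mean()
        out[f"{ch}_norm"] = norm
        out[f"z_{ch}"] = z
        out[f"n_iter_{ch}"] = n_iter
    return out


def call_outliers(summaries: pd.DataFrame, z_cutoff: float = 3.0,
                  single_pass: bool = False) -> pd.DataFrame:
    """Channel z-scores and the outlier category per strain.

    ``category``: ``none``, ``gfp_only``, ``mcherry_only`` or ``both``,
    from the per-channel |z| > cutoff flags (iterated reference set).
    Accepts raw or already-normalized summaries; z-scores are recomputed
    so the call never depends on column staleness.
    """
    normed = normalize_library(summaries, z_cutoff=z_cutoff, single_pass=single_pass,
                               zero_sd="raise")
    g = np.abs(normed["z_gfp"].to_numpy()) > z_cutoff
    m = np.abs(normed["z_mcherry"].to_numpy()) > z_cutoff
    category = np.where(g & m, "both",
                        np.where(g, "gfp_only",
                                 np.where(m, "mcherry_only", "none")))
    normed["category"] = category
    return normed


def _fit_cv_trend(mean: np.ndarray, cv: np.ndarray, n_bins: int = 10):
    """CV-mean trend on non-outlier strains: power law ``a*mean^b + c``
    least-squares fit to log-binned medians; falls back to the global
    median CV (constant trend) when the fit is not possible."""
    ok = np.isfinite(mean) & np.isfinite(cv) & (mean > 0)
    mean, cv = mean[ok], cv[ok]
    fallback_level = float(np.median(cv)) if len(cv) else np.nan

    def fallback(_x):
        return np.full_like(np.asarray(_x, dtype=float), fallback_level)

    if len(mean) < MIN_STRAINS:
        warnings.warn("too few strains for a CV-mean trend fit; using global median CV")
        return fallback
    edges = np.quantile(np.log(mean), np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, np.log(mean), side="right") - 1, 0, n_bins - 1)
    bx, by = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() >= 3:
            bx.append(np.exp(np.median(np.log(mean[sel]))))
            by.append(np.median(cv[sel]))
    if len(bx) < 3:
        return fallback
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, a, b, c: a * np.power(x, b) + c,
                np.array(bx), np.array(by),
                p0=[0.1, -0.5, fallback_level],
                bounds=([0.0, -3.0, 0.0], [np.inf, 0.0, np.inf]),
                maxfev=10_000)
    except (RuntimeError, ValueError):
        warnings.warn("CV-mean trend fit failed; using global median CV")
        return fallback
    a, b, c = popt
    return lambda x: a * np.power(np.asarray(x, dtype=float), b) + c


def classify_profiles(outliers: pd.DataFrame, noise_k: float = 3.0,
                      z_cutoff: float = 3.0) -> pd.DataFrame:
    """Assign profiles on the noise-vs-mean plane.

    GFP outliers with z < -cutoff split into profile 2 (CV residual above
    ``noise_k`` robust SDs of the non-outlier residuals, i.e. genuinely
    noisy) versus profile 3 (CV on the trend); z > +cutoff is profile 4
    regardless of noise.  Non-GFP-outlier strains are profile 1.  Adds
    ``noise_residual`` and ``profile`` columns.
    """
    out = outliers.copy()
    is_gfp_out = out["category"].isin(["gfp_only", "both"]).to_numpy()
    mean = out["gfp_norm"].to_numpy(float)
    cv = out["gfp_cv"].to_numpy(float)
    trend = _fit_cv_trend(mean[~is_gfp_out], cv[~is_gfp_out])
    residual = cv - trend(mean)
    ref_resid = residual[~is_gfp_out]
    ref_resid = ref_resid[np.isfinite(ref_resid)]
    mad_sd = float(stats.median_abs_deviation(ref_resid, scale="normal"))
    threshold = noise_k * mad_sd
    z = out["z_gfp"].to_numpy(float)
    profile = np.ones(len(out), dtype=int)
    profile[is_gfp_out & (z > z_cutoff)] = 4
    low = is_gfp_out & (z < -z_cutoff)
    profile[low & (residual > threshold)] = 2
    profile[low & (residual <= threshold)] = 3
    out["noise_residual"] = residual
    out["profile"] = profile
    return out


@dataclass(frozen=True)
class ScreenResult:
    summaries: pd.DataFrame  # normalized, with z, category, profile columns
    counts: dict[str, int]   # outlier category counts
    profile_counts: dict[int, int]


def screen_library(summaries: pd.DataFrame, z_cutoff: float = 3.0,
                   noise_k: float = 3.0, single_pass: bool = False) -> ScreenResult:
    """Normalize, call outliers and classify profiles in one pass."""
    called = call_outliers(summaries, z_cutoff=z_cutoff, single_pass=single_pass)
    labeled = classify_profiles(called, noise_k=noise_k, z_cutoff=z_cutoff)
    counts = {k: int(v) for k, v in
              labeled["category"].value_counts().items() if k != "none"}
    for key in ("gfp_only", "mcherry_only", "both"):
        counts.setdefault(key, 0)
    profile_counts = {int(k): int(v) for k, v in
                      labeled["profile"].value_counts().sort_index().items()}
    return ScreenResult(summaries=labeled, counts=counts, profile_counts=profile_counts)


def compare_noise(strain_a: pd.DataFrame, strain_b: pd.DataFrame,
                  n_boot: int = 10_000, seed: int | np.random.Generator = 0,
                  channel: str = "gfp") -> dict:
    """Bootstrap test for a CV difference between two strains.

    Resamples cells with replacement within each strain, recomputes the
    CV difference (b - a), and reports the observed difference, a 95%
    percentile interval and a two-sided p-value from the bootstrap
    distribution's overlap with zero (with the usual +1 pseudocount).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def values(df: pd.DataFrame) -> np.ndarray:
        x = df[df["gated"]][channel] if "gated" in df.columns else df[channel]
        return x.to_numpy(float)

    a, b = values(strain_a), values(strain_b)
    if len(a) < MIN_CELLS or len(b) < MIN_CELLS:
        raise ValueError(f"compare_noise needs >= {MIN_CELLS} cells per strain")

    def cv(x: np.ndarray, axis=None) -> np.ndarray:
        return x.std(ddof=1, axis=axis) / x.mean(axis=axis)

    observed = float(cv(b) - cv(a))
    deltas = np.empty(n_boot)
    chunk = max(1, min(n_boot, 50_000_000 // max(len(a) + len(b), 1)))
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        ra = a[rng.integers(0, len(a), size=(k, len(a)))]
        rb = b[rng.integers(0, len(b), size=(k, len(b)))]
        deltas[done:done + k] = cv(rb, axis=1) - cv(ra, axis=1)
        done += k
    lo, hi = np.quantile(deltas, [0.025, 0.975])
    # two-sided p: can the bootstrap distribution be shifted to cover 0?
    shifted = deltas - observed  # approximate null distribution of the difference
    r = int(np.sum(np.abs(shifted) >= abs(observed)))
    p = (r + 1) / (n_boot + 1)
    return {"delta_cv": observed, "ci_low": float(lo), "ci_high": float(hi),
            "p_value": float(p), "n_boot": n_boot}


def read_summary_table(path) -> pd.DataFrame:
    """Read a per-strain expression table (TSV) for reanalysis mode.

    Expected columns: ``strain, gfp_mean, gfp_cv, mcherry_mean,
    mcherry_cv`` (extra columns pass through).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["strain", "gfp_mean", "gfp_cv", "mcherry_mean", "mcherry_cv"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    return df
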