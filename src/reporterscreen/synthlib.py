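"""Synthetic dual-reporter libraries with known ground truth.

Generates flow-cytometry-style single-cell event tables for a strain
library in which a GFP reporter sits at a different genomic locus in
every strain and an mCherry control sits at one fixed locus.  The
generator encodes the statistical structure the downstream screen
assumes:

* lognormal single-cell fluorescence with a per-cell *extrinsic* factor
  shared between the two channels (cell size, global machinery) and a
  channel-specific *intrinsic* residual, so that
  ``total_cv^2 = (1 + extrinsic_cv^2) * (1 + intrinsic_cv^2) - 1``;
* four expression regimes ("profiles"): 1 = normal, 2 = low mean / high
  noise, 3 = low mean / low noise, 4 = high mean / low noise; mCherry is
  profile-independent;
* linear spectral crosstalk between the two detector channels, applied
  after autofluorescence;
* a small fraction of cells (loss of heterozygosity) in which one
  reporter's biological signal is absent;
* insertion sites on a synthetic genome, with profile-4 sites placed
  near a designated target-gene set and all others uniformly.

Everything is driven by :class:`numpy.random.Generator`; identical
configuration and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cyto import CrosstalkMatrix

__all__ = [
    "LibraryConfig",
    "TrueStrainState",
    "SyntheticGenome",
    "PlacementRule",
    "synthetic_genome",
    "simulate_strain_events",
    "simulate_library",
    "simulate_qpcr_replicates",
    "synthetic_library_table",
    "write_chrom_sizes",
    "write_bed",
]

#: (mean multiplier, CV multiplier) relative to profile 1, indexed by profile.
#: Profile 2 = silencing-like (low mean, high noise), profile 3 =
#: interference-like (low mean, normal noise), profile 4 = clustering-like
#: (high mean, slightly tighter noise).
DEFAULT_PROFILE_EFFECTS: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (0.6, 3.0),
    (0.6, 1.0),
    (1.6, 0.8),
)


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters of the synthetic library.

    Units: means and autofluorescence are arbitrary fluorescence units;
    all CVs are dimensionless (SD/mean); ``loh_rate`` is a per-cell
    probability.  ``strain_mean_cv`` is the strain-to-strain lognormal
    spread of true means around the profile baseline — it is what gives
    the library a non-degenerate SD for the 3-SD outlier rule.
    """

    n_strains: int = 1327
    events_per_strain: int = 5000
    profile_fractions: tuple[float, float, float, float] = (0.975, 0.008, 0.008, 0.009)
    profile_effects: tuple[tuple[float, float], ...] = DEFAULT_PROFILE_EFFECTS
    base_mean: float = 1000.0
    base_cv: float = 0.25
    extrinsic_cv: float = 0.15
    crosstalk: CrosstalkMatrix = field(default_factory=lambda: CrosstalkMatrix(0.03, 0.08))
    loh_rate: float = 0.015
    autofluorescence_mean: float = 20.0
    autofluorescence_cv: float = 0.3
    strain_mean_cv: float = 0.05
    cv_mean_exponent: float = -0.25
    scatter_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.asarray(self.profile_fractions, dtype=float)
        if frac.shape != (4,):
            raise ValueError("profile_fractions must have exactly 4 entries")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile_fractions sum to {frac.sum()}, expected 1")
        if frac.argmax() != 0:
            raise ValueError("profile 1 must be the most common class")
        if np.any(frac < 0):
            raise ValueError("profile_fractions must be non-negative")
        for name in ("base_mean", "base_cv", "extrinsic_cv", "loh_rate",
                     "autofluorescence_mean", "autofluorescence_cv", "strain_mean_cv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not self.loh_rate < 1:
            raise ValueError("loh_rate must be < 1")
        if self.n_strains < 1 or self.events_per_strain < 1:
            raise ValueError("n_strains and events_per_strain must be >= 1")
        if len(self.profile_effects) != 4 or self.profile_effects[0] != (1.0, 1.0):
            raise ValueError("profile_effects must list 4 profiles with profile 1 == (1.0, 1.0)")


@dataclass(frozen=True)
class InsertionSite:
    strain_id: str
    chrom: str
    position: int  # 0-based bp


@dataclass(frozen=True)
class TrueStrainState:
    """Ground truth for one strain (the generator's answer key)."""

    strain_id: str
    true_profile: int
    true_gfp_mean: float
    true_gfp_cv: float
    true_mcherry_mean: float
    true_mcherry_cv: float
    insertion_site: InsertionSite | None = None


@dataclass(frozen=True)
class SyntheticGenome:
    """Chromosome lengths plus a target-gene annotation (BED-like)."""

    chromosomes: list[tuple[str, int]]
    features: pd.DataFrame  # columns: chrom, start, end, name, score, strand

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        f = self.features
        if len(f):
            if (f["start"] < 0).any() or (f["start"] >= f["end"]).any():
                raise ValueError("features must satisfy 0 <= start < end")
            ends = f["chrom"].map(lengths)
            if ends.isna().any() or (f["end"] > ends).any():
                raise ValueError("features must lie within their chromosome")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class PlacementRule:
    """How profile-4 insertion sites relate to the target-gene set:
    uniform offset within ``window`` bp of a random feature start."""

    window: int = 2000


def synthetic_genome(n_chrom: int = 16, mean_length: int = 750_000,
                     n_features: int = 405, seed: int = 0) -> SyntheticGenome:
    """A yeast-scale genome (~12 Mb over 16 chromosomes by default) with a
    target-gene set scattered uniformly, gene length 500–3000 bp, random
    strand."""
    rng = np.random.default_rng(seed)
    lengths = np.maximum(50_000, rng.normal(mean_length, mean_length * 0.4, n_chrom).astype(int))
    chroms = [(f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)]
    probs = lengths / lengths.sum()
    ci = rng.choice(n_chrom, size=n_features, p=probs)
    gene_len = rng.integers(500, 3000, n_features)
    starts = (rng.random(n_features) * (lengths[ci] - gene_len)).astype(int)
    features = pd.DataFrame({
        "chrom": [chroms[i][0] for i in ci],
        "start": starts,
        "end": starts + gene_len,
        "name": [f"TGT{i + 1:03d}" for i in range(n_features)],
        "score": 0,
        "strand": rng.choice(["+", "-"], n_features),
    })
    return SyntheticGenome(chromosomes=chroms, features=features)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size)


def intrinsic_cv(total_cv: float, extrinsic_cv: float) -> float:
    """Residual channel-specific CV such that the product of the shared
    extrinsic factor and the intrinsic factor has the requested total CV.

    For independent unit-mean lognormals, CVs combine as
    ``(1 + total^2) = (1 + ext^2)(1 + int^2)``.
    """
    if total_cv < extrinsic_cv:
        raise ValueError(
            f"total CV {total_cv} < extrinsic CV {extrinsic_cv}: no valid intrinsic CV")
    ratio = (1.0 + total_cv ** 2) / (1.0 + extrinsic_cv ** 2) - 1.0
    return math.sqrt(max(ratio, 0.0))


def simulate_strain_events(state: TrueStrainState, cfg: LibraryConfig,
                           seed: int | np.random.Generator) -> pd.DataFrame:
    """Single-cell events for one strain.

    Per cell: a shared extrinsic lognormal factor scales both channels;
    channel-specific intrinsic lognormal factors bring each channel to its
    strain's total CV; autofluorescence is added; the crosstalk matrix
    mixes the two emitted signals into the raw detector channels; FSC/SSC
    are lognormal and correlated (``cfg.scatter_rho``) with the extrinsic
    factor.  With probability ``loh_rate`` one channel's biological signal
    is zeroed (autofluorescence kept).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.events_per_strain
    for v in (state.true_gfp_mean, state.true_gfp_cv,
              state.true_mcherry_mean, state.true_mcherry_cv):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"non-finite or negative strain parameter: {v}")

    ext = _lognormal_unit_mean(rng, cfg.extrinsic_cv, n)

    def channel(mean: float, cv: float) -> np.ndarray:
        if mean == 0:
            return np.zeros(n)
        intr = _lognormal_unit_mean(rng, intrinsic_cv(cv, cfg.extrinsic_cv), n)
        return mean * ext * intr

    gfp = channel(state.true_gfp_mean, state.true_gfp_cv)
    mch = channel(state.true_mcherry_mean, state.true_mcherry_cv)

    # LOH: zero one reporter's biological signal in a small cell fraction
    if cfg.loh_rate > 0:
        lost = rng.random(n) < cfg.loh_rate
        which = rng.random(n) < 0.5
        gfp[lost & which] = 0.0
        mch[lost & ~which] = 0.0

    af1 = cfg.autofluorescence_mean * _lognormal_unit_mean(rng, cfg.autofluorescence_cv, n)
    af2 = cfg.autofluorescence_mean * _lognormal_unit_mean(rng, cfg.autofluorescence_cv, n)
    emitted1 = gfp + af1
    emitted2 = mch + af2
    m = cfg.crosstalk
    ch1_raw = emitted1 + m.m12 * emitted2
    ch2_raw = m.m21 * emitted1 + emitted2

    # FSC/SSC share the extrinsic factor's log with correlation scatter_rho
    log_ext = np.log(ext) if cfg.extrinsic_cv > 0 else None
    sigma_ext = math.sqrt(math.log1p(cfg.extrinsic_cv ** 2))

    def scatter(mean: float, cv: float) -> np.ndarray:
        sigma = math.sqrt(math.log1p(cv * cv))
        mu = math.log(mean) - sigma * sigma / 2.0
        z = rng.standard_normal(n)
        if log_ext is None or cfg.scatter_rho == 0:
            return np.exp(mu + sigma * z)
        z_ext = (log_ext + sigma_ext ** 2 / 2.0) / sigma_ext
        rho = cfg.scatter_rho
        return np.exp(mu + sigma * (rho * z_ext + math.sqrt(1 - rho * rho) * z))

    fsc = scatter(50_000.0, 0.30)
    ssc = scatter(30_000.0, 0.35)

    return pd.DataFrame({
        "cell_id": np.arange(n),
        "fsc": fsc,
        "ssc": ssc,
        "ch1_raw": ch1_raw,
        "ch2_raw": ch2_raw,
    })


def _uniform_positions(rng: np.random.Generator, genome: SyntheticGenome,
                       size: int) -> list[tuple[str, int]]:
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    ci = rng.choice(len(lengths), size=size, p=lengths / lengths.sum())
    pos = (rng.random(size) * lengths[ci]).astype(int)
    return [(genome.chromosomes[i][0], int(p)) for i, p in zip(ci, pos)]


def _reference_point(row: pd.Series) -> int:
    return int(row["end"]) if row["strand"] == "-" else int(row["start"])


def assign_true_states(cfg: LibraryConfig, genome: SyntheticGenome,
                       placement: PlacementRule,
                       rng: np.random.Generator) -> list[TrueStrainState]:
    """Draw per-strain ground truth: profile labels by ``profile_fractions``,
    strain-level mean dispersion, CV from the profile's CV multiplier and a
    mild noise-vs-mean scaling, and insertion sites (profile 4 near target
    starts, everything else uniform)."""
    if placement.window > max(l for _, l in genome.chromosomes):
        raise ValueError("placement window larger than any chromosome")
    n = cfg.n_strains
    profiles = rng.choice(4, size=n, p=np.asarray(cfg.profile_fractions)) + 1
    gfp_disp = _lognormal_unit_mean(rng, cfg.strain_mean_cv, n)
    mch_disp = _lognormal_unit_mean(rng, cfg.strain_mean_cv, n)
    uniform_sites = _uniform_positions(rng, genome, n)

    lengths = dict(genome.chromosomes)
    states = []
    for i in range(n):
        p = int(profiles[i])
        mean_mult, cv_mult = cfg.profile_effects[p - 1]
        rel_mean = mean_mult * gfp_disp[i]
        gfp_mean = cfg.base_mean * rel_mean
        gfp_cv = cfg.base_cv * (rel_mean ** cfg.cv_mean_exponent) * cv_mult
        if p == 4 and len(genome.features):
            feat = genome.features.iloc[int(rng.integers(len(genome.features)))]
            ref = _reference_point(feat)
            offset = int(rng.integers(-placement.window, placement.window + 1))
            pos = int(np.clip(ref + offset, 0, lengths[feat["chrom"]] - 1))
            site = InsertionSite(f"strain{i + 1:04d}", str(feat["chrom"]), pos)
        else:
            chrom, pos = uniform_sites[i]
            site = InsertionSite(f"strain{i + 1:04d}", chrom, pos)
        states.append(TrueStrainState(
            strain_id=f"strain{i + 1:04d}",
            true_profile=p,
            true_gfp_mean=gfp_mean,
            true_gfp_cv=gfp_cv,
            true_mcherry_mean=cfg.base_mean * mch_disp[i],
            true_mcherry_cv=cfg.base_cv,
            insertion_site=site,
        ))
    return states


def simulate_library(cfg: LibraryConfig, genome: SyntheticGenome | None = None,
                     placement: PlacementRule = PlacementRule(),
                     ) -> tuple[list[TrueStrainState], dict[str, pd.DataFrame],
                                dict[str, pd.DataFrame]]:
    """Full library: ground-truth states, one event table per strain, and the
    three control tables (GFP-only, mCherry-only, blank) the crosstalk and
    background estimation needs.

    Returns ``(states, events_by_strain, controls)`` where ``controls`` has
    keys ``gfp_only``, ``mcherry_only`` and ``blank``.
    """
    if genome is None:
        genome = synthetic_genome(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    states = assign_true_states(cfg, genome, placement, rng)
    events = {s.strain_id: simulate_strain_events(s, cfg, rng) for s in states}

    def control(gfp_mean: float, mch_mean: float) -> pd.DataFrame:
        st = TrueStrainState("control", 1, gfp_mean, cfg.base_cv,
                             mch_mean, cfg.base_cv)
        return simulate_strain_events(st, replace(cfg, loh_rate=0.0), rng)

    controls = {
        "gfp_only": control(cfg.base_mean, 0.0),
        "mcherry_only": control(0.0, cfg.base_mean),
        "blank": control(0.0, 0.0),
    }
    return states, events, controls


def simulate_qpcr_replicates(true_quantities: dict[str, float], n_reps: int = 3,
                             noise_cv: float = 0.15,
                             seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Replicate qPCR-style quantities with lognormal multiplicative noise.

    ``true_quantities`` maps condition label -> true linear-scale level.
    Columns of the result: ``condition, replicate, quantity``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for cond, level in true_quantities.items():
        noise = _lognormal_unit_mean(rng, noise_cv, n_reps)
        for r in range(n_reps):
            rows.append((cond, r + 1, level * noise[r]))
    return pd.DataFrame(rows, columns=["condition", "replicate", "quantity"])


def synthetic_library_table(n_strains: int = 1327, n_profile2: int = 10,
                            n_profile3: int = 10, n_profile4: int = 10,
                            n_mcherry_only: int = 1, n_both: int = 2,
                            seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a library-wide per-strain expression table.

    This is *generated* data, not measured: a strain-level summary table
    (mean and CV per channel) whose ground truth contains 30 GFP-only
    outliers split over profiles 2/3/4, plus mCherry-only and dual
    outliers, against a backdrop of normal strains with ~5% strain-to-
    strain spread.  Outlier effect sizes are many library SDs, as in the
    real screen where confirmed outliers are far outside the cloud.

    Columns: ``strain, gfp_mean, gfp_cv, mcherry_mean, mcherry_cv,
    true_profile, true_category``.
    """
    rng = np.random.default_rng(seed)
    n_out = n_profile2 + n_profile3 + n_profile4 + n_mcherry_only + n_both
    if n_out >= n_strains:
        raise ValueError("more outliers than strains")
    base_cv, spread = 0.25, 0.05

    # Backdrop means are truncated at +/-2.5 SD so the designed outliers are
    # by construction the only strains beyond the 3-SD rule.
    def backdrop(size: int) -> np.ndarray:
        z = stats.truncnorm.rvs(-2.5, 2.5, size=size, random_state=rng)
        return np.exp(spread * z - spread ** 2 / 2)

    gfp_mean = backdrop(n_strains)
    mch_mean = backdrop(n_strains)
    gfp_cv = base_cv * rng.lognormal(0, 0.08, n_strains)
    mch_cv = base_cv * rng.lognormal(0, 0.08, n_strains)
    profile = np.ones(n_strains, dtype=int)
    category = np.array(["none"] * n_strains, dtype=object)

    idx = rng.permutation(n_strains)[:n_out]
    k = 0
    for count, prof, cat in ((n_profile2, 2, "gfp_only"),
                             (n_profile3, 3, "gfp_only"),
                             (n_profile4, 4, "gfp_only"),
                             (n_mcherry_only, 1, "mcherry_only"),
                             (n_both, 2, "both")):
        for _ in range(count):
            i = idx[k]; k += 1
            profile[i] = prof
            category[i] = cat
            if cat in ("gfp_only", "both"):
                if prof == 4:
                    gfp_mean[i] *= 1.6
                else:
                    gfp_mean[i] *= 0.6
                if prof == 2:
                    gfp_cv[i] *= 3.0
            if cat in ("mcherry_only", "both"):
                mch_mean[i] *= rng.choice([0.6, 1.5])
    return pd.DataFrame({
        "strain": [f"strain{i + 1:04d}" for i in range(n_strains)],
        "gfp_mean": gfp_mean,
        "gfp_cv": gfp_cv,
        "mcherry_mean": mch_mean,
        "mcherry_cv": mch_cv,
        "true_profile": profile,
        "true_category": category,
    })


def write_chrom_sizes(genome: SyntheticGenome, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def write_bed(features: pd.DataFrame, path) -> None:
    features[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)
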