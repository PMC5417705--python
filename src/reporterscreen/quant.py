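"""Replicate-level quantification for ChIP / 3C / RT-qPCR readouts.

Measurements arrive as a tidy table with columns
``assay, target, condition, replicate, quantity`` where ``quantity`` is
a positive linear-scale abundance (Cq values already converted with the
amplification efficiency; :func:`cq_to_quantity` does the conversion).

Supported operations:

* reference normalization — e.g. ChIP signals divided by the profile-1
  strain, or 3C signals divided by the positive-control amplicon; the
  reported value is a ratio of group means with a delta-method SE;
* fold change between two conditions (e.g. +/- methionine) after
  per-replicate normalization to an internal control amplicon (positive
  control for 3C, a housekeeping gene such as ACT1 for RT-PCR), with a
  Welch t-test on log-transformed normalized replicates;
* group comparisons of several strains/profiles against a reference
  group, optionally Benjamini-Hochberg corrected across targets.

Tests default to log scale because qPCR noise is multiplicative;
``log_scale=False`` switches to a raw-scale Welch test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cq_to_quantity",
    "read_measures",
    "normalize_to_reference",
    "welch_test",
    "fold_change",
    "group_compare",
]

COLUMNS = ["assay", "target", "condition", "replicate", "quantity"]


def cq_to_quantity(cq, efficiency: float = 2.0):
    """Convert quantification-cycle values to linear-scale quantities,
    ``quantity = E ** (-Cq)`` with per-cycle amplification efficiency E
    (2 = perfect doubling)."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return np.power(efficiency, -np.asarray(cq, dtype=float))


def read_measures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["quantity"] <= 0).any():
        raise ValueError(f"{path}: quantities must be positive")
    return df


def _group_quantities(measures: pd.DataFrame, **keys) -> np.ndarray:
    sel = np.ones(len(measures), dtype=bool)
    for col, val in keys.items():
        sel &= (measures[col] == val).to_numpy()
    return measures.loc[sel, "quantity"].to_numpy(float)


def normalize_to_reference(measures: pd.DataFrame, reference: str,
                           by: str = "condition") -> pd.DataFrame:
    """Per (target, condition) ratio to the reference group's mean.

    ``by`` selects whether ``reference`` names a condition (normalize each
    condition's mean within a target to the reference condition, as for
    ChIP signals vs the profile-1 strain) or a target (normalize across
    amplicons to e.g. the 3C positive control, within each condition).

    ``value = mean(group) / mean(reference)``; SE by first-order (delta
    method) propagation for a ratio of independent means.  The reference
    group itself is reported as exactly 1 with the SE of its own
    replicate spread.
    """
    if by not in ("condition", "target"):
        raise ValueError("by must be 'condition' or 'target'")
    rows = []
    for (assay, target, condition), grp in measures.groupby(
            ["assay", "target", "condition"], sort=False):
        if by == "condition":
            ref = _group_quantities(measures, assay=assay, target=target,
                                    condition=reference)
            is_ref = condition == reference
        else:
            ref = _group_quantities(measures, assay=assay, target=reference,
                                    condition=condition)
            is_ref = target == reference
        if len(ref) < 2:
            raise ValueError(
                f"reference {reference!r} needs >= 2 replicates for {assay}/{target}/{condition}")
        if ref.mean() <= 0:
            raise ValueError(f"non-positive reference mean for {assay}/{target}/{condition}")
        x = grp["quantity"].to_numpy(float)
        mx, mr = x.mean(), ref.mean()
        sex = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        if is_ref:
            value, se = 1.0, sex / mx
        else:
            ser = ref.std(ddof=1) / np.sqrt(len(ref))
            value = mx / mr
            se = value * np.sqrt((sex / mx) ** 2 + (ser / mr) ** 2)
        rows.append({"assay": assay, "target": target, "condition": condition,
                     "value": value, "se": se, "n": len(x)})
    return pd.DataFrame(rows)


def welch_test(a: np.ndarray, b: np.ndarray, log_scale: bool = True,
               axis: int = -1) -> dict:
    """Welch two-sample t-test of b vs a, by default on log quantities.

    Axis-aware (vectorizes over leading axes for simulation studies).
    Returns the ratio estimate mean(b)/mean(a) (geometric on log scale),
    its 95% CI, and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if log_scale:
        a, b = np.log(a), np.log(b)
    res = stats.ttest_ind(b, a, equal_var=False, axis=axis)
    ci = res.confidence_interval(0.95)
    diff = np.mean(b, axis=axis) - np.mean(a, axis=axis)
    if log_scale:
        est, lo, hi = np.exp(diff), np.exp(ci.low), np.exp(ci.high)
    else:
        est, lo, hi = diff, ci.low, ci.high
    return {"estimate": est, "ci_low": lo, "ci_high": hi,
            "p_value": res.pvalue, "df": res.df}


def _per_replicate_control_norm(measures: pd.DataFrame, target: str,
                                control_target: str) -> pd.DataFrame:
    """Divide each replicate's quantity by the internal-control quantity
    of the same (assay, condition, replicate) batch; batches lacking the
    control are dropped with a warning."""
    ctrl = measures[measures["target"] == control_target].set_index(
        ["assay", "condition", "replicate"])["quantity"]
    tgt = measures[measures["target"] == target].copy()
    keys = list(zip(tgt["assay"], tgt["condition"], tgt["replicate"]))
    have = [k in ctrl.index for k in keys]
    if not all(have):
        dropped = [k for k, h in zip(keys, have) if not h]
        warnings.warn(f"batches without internal control {control_target!r} "
                      f"dropped: {dropped}")
        tgt = tgt[have]
        keys = [k for k, h in zip(keys, have) if h]
    if len(tgt) == 0:
        raise ValueError(f"no batch of target {target!r} has internal control "
                         f"{control_target!r}")
    tgt["quantity"] = tgt["quantity"].to_numpy(float) / ctrl.loc[keys].to_numpy(float)
    return tgt


def fold_change(measures: pd.DataFrame, target: str, condition_a: str,
                condition_b: str, control_target: str | None = None,
                log_scale: bool = True) -> dict:
    """Fold change of ``target`` between two conditions,
    ``fold = mean(condition_b) / mean(condition_a)``.

    With ``control_target`` each replicate is first divided by the
    internal control measured in the same batch (3C positive control,
    RT-PCR housekeeping gene).  The p-value is a Welch t-test on the
    (log) normalized replicates.
    """
    df = (_per_replicate_control_norm(measures, target, control_target)
          if control_target else measures[measures["target"] == target])
    a = _group_quantities(df, condition=condition_a)
    b = _group_quantities(df, condition=condition_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("fold_change needs >= 2 replicates per condition")
    test = welch_test(a, b, log_scale=log_scale)
    fold = float(b.mean() / a.mean())
    se = fold * float(np.sqrt((a.std(ddof=1) / np.sqrt(len(a)) / a.mean()) ** 2 +
                              (b.std(ddof=1) / np.sqrt(len(b)) / b.mean()) ** 2))
    return {"target": target, "condition_a": condition_a, "condition_b": condition_b,
            "fold": fold, "se": se, "p_value": float(test["p_value"]),
            "ci_low": float(test["ci_low"]), "ci_high": float(test["ci_high"]),
            "n_a": len(a), "n_b": len(b)}


def group_compare(measures: pd.DataFrame, reference_group: str,
                  group_col: str = "condition", log_scale: bool = True,
                  bh_correct: bool = False) -> pd.DataFrame:
    """Welch tests of every group against a reference group, per target.

    Groups are levels of ``group_col`` (condition labels, strain ids or
    profile names).  Effects are ratios of means with 95% CIs.  Raw
    p-values by default; ``bh_correct=True`` adds a Benjamini-Hochberg
    ``p_adj`` column across all reported tests.
    """
    rows = []
    for (assay, target), sub in measures.groupby(["assay", "target"], sort=False):
        ref = sub.loc[sub[group_col] == reference_group, "quantity"].to_numpy(float)
        if len(ref) < 2:
            raise ValueError(f"reference group {reference_group!r} needs >= 2 "
                             f"replicates for {assay}/{target}")
        for group, grp in sub.groupby(group_col, sort=False):
            if group == reference_group:
                continue
            x = grp["quantity"].to_numpy(float)
            if len(x) < 2:
                raise ValueError(f"group {group!r} needs >= 2 replicates")
            flagged = (x.std(ddof=1) == 0 or ref.std(ddof=1) == 0) and min(len(x), len(ref)) < 3
            test = welch_test(ref, x, log_scale=log_scale)
            rows.append({"assay": assay, "target": target, "group": group,
                         "effect": float(test["estimate"]),
                         "ci_low": float(test["ci_low"]),
                         "ci_high": float(test["ci_high"]),
                         "p_value": float(test["p_value"]) if not flagged else np.nan,
                         "flagged": bool(flagged), "n": len(x), "n_ref": len(ref)})
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_adj"] = adj
    return out
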