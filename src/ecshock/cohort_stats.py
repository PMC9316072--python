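"""Stage-wise descriptive statistics of the cohort.

Covers the three descriptive analyses run before any modelling: relative
changes of each channel versus the subject's own baseline (medians with
quartiles), paired Wilcoxon signed-rank tests of each LBNP stage against
baseline, and Pearson/Spearman correlations with the echo reference stroke
volume — population-wide and per subject — graded by Cohen's strength
classes (|rho| >= 0.1 small, >= 0.3 medium, >= 0.5 large, boundaries
inclusive).

Wilcoxon policy: zero differences are dropped before ranking; the exact
null distribution is used for n <= 25 non-zero pairs without ties, the
normal approximation with continuity and tie correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, EvaluationError
from .protocol import BASELINE

__all__ = [
    "relative_changes",
    "WilcoxonResult",
    "wilcoxon_vs_baseline",
    "wilcoxon_null_rejection_rate",
    "cohen_class",
    "CorrelationResult",
    "correlations",
    "stage_comparison_table",
]

_EXACT_MAX_N = 25


def relative_changes(stage_values: pd.DataFrame, value_cols,
                     baseline: str = BASELINE) -> pd.DataFrame:
    """Each subject's stage values divided by their own baseline value.

    ``stage_values`` holds one row per (subject_id, stage). Baseline rows
    come out exactly 1. Subjects with a zero/missing baseline for a column
    are excluded for that column with a warning.
    """
    if baseline not in set(stage_values["stage"]):
        raise DataError(f"no {baseline!r} rows present")
    value_cols = list(value_cols)
    base = (stage_values[stage_values["stage"] == baseline]
            .set_index("subject_id")[value_cols])
    bad = base.columns[(base == 0).any() | base.isna().any()]
    for col in bad:
        n = int(((base[col] == 0) | base[col].isna()).sum())
        warnings.warn(f"{col}: {n} subject(s) with zero/missing baseline excluded")
    out = stage_values[["subject_id", "stage"]].copy()
    denom = base.reindex(stage_values["subject_id"])
    denom = denom.mask(denom == 0)
    for col in value_cols:
        out[col] = stage_values[col].to_numpy() / denom[col].to_numpy()
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    n_nonzero: int
    degenerate: bool
    method: str


def wilcoxon_vs_baseline(values, baseline_values) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test against baseline.

    All-zero difference vectors are degenerate and reported as p = 1.
    """
    x = np.asarray(values, dtype=float)
    b = np.asarray(baseline_values, dtype=float)
    if x.shape != b.shape or x.ndim != 1:
        raise DataError("paired vectors must be 1-D and equal length")
    d = x - b
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(1.0, 0.0, 0, True, "degenerate")
    ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= _EXACT_MAX_N and not ties:
        method = "exact"
        res = sps.wilcoxon(nz, zero_method="wilcox", method="exact")
    else:
        method = "approx"
        res = sps.wilcoxon(nz, zero_method="wilcox", method="approx",
                           correction=True)
    return WilcoxonResult(float(res.pvalue), float(res.statistic),
                          int(nz.size), False, method)


def wilcoxon_null_rejection_rate(n: int = 29, reps: int = 10_000,
                                 alpha: float = 0.05, seed=None) -> float:
    """Monte-Carlo type-I error of the test on Gaussian null pairs.

    Vectorised over replicates using the same normal-approximation p-value
    the package applies at this sample size (continuous data, no ties
    almost surely, n > 25).
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((reps, n))
    ranks = sps.rankdata(np.abs(d), axis=1)
    w_pos = np.where(d > 0, ranks, 0.0).sum(axis=1)
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (np.abs(w_pos - mu) - 0.5) / sigma  # continuity-corrected
    p = 2.0 * sps.norm.sf(z)
    return float(np.mean(p < alpha))


def cohen_class(rho: float) -> str:
    """Cohen's correlation-strength class of |rho| (lower edges inclusive)."""
    a = abs(rho)
    if not np.isfinite(a) or a > 1:
        raise EvaluationError(f"invalid correlation {rho}")
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small"
    return "below-small"


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    scope: str  # "population" | "per-subject"
    pearson: float
    spearman: float
    cohen: str
    per_subject: pd.DataFrame | None = None  # subject_id, pearson, spearman
    q25: float | None = None
    q75: float | None = None


def _corr_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3:
        raise EvaluationError("need >= 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EvaluationError("zero variance: correlation undefined")
    return (float(sps.pearsonr(x, y).statistic),
            float(sps.spearmanr(x, y).statistic))


def correlations(table: pd.DataFrame, x_col: str, y_col: str,
                 scope: str = "population",
                 subject_col: str = "subject_id") -> CorrelationResult:
    """Pearson/Spearman correlation between two columns.

    scope="population" pools all rows; scope="per-subject" computes one
    coefficient per subject (skipping subjects with < 3 complete pairs or
    zero variance) and summarises the distribution by median and quartiles.
    """
    data = table[[subject_col, x_col, y_col]].dropna()
    if scope == "population":
        rp, rs = _corr_pair(data[x_col].to_numpy(float), data[y_col].to_numpy(float))
        return CorrelationResult(x_col, scope, rp, rs, cohen_class(rp))
    if scope != "per-subject":
        raise EvaluationError(f"unknown scope {scope!r}")
    rows = []
    for sid, grp in data.groupby(subject_col, sort=True):
        x = grp[x_col].to_numpy(float)
        y = grp[y_col].to_numpy(float)
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        rp, rs = _corr_pair(x, y)
        rows.append({"subject_id": sid, "pearson": rp, "spearman": rs})
    if not rows:
        raise EvaluationError("no subject with enough complete pairs")
    per = pd.DataFrame(rows)
    med_p = float(per["pearson"].median())
    return CorrelationResult(
        x_col, scope, med_p, float(per["spearman"].median()),
        cohen_class(med_p), per_subject=per,
        q25=float(per["pearson"].quantile(0.25)),
        q75=float(per["pearson"].quantile(0.75)),
    )


def stage_comparison_table(stage_values: pd.DataFrame, value_cols,
                           baseline: str = BASELINE) -> pd.DataFrame:
    """Per (channel, stage): median relative change with quartiles and the
    paired Wilcoxon p-value against baseline."""
    value_cols = list(value_cols)
    rel = relative_changes(stage_values, value_cols, baseline=baseline)
    base = (stage_values[stage_values["stage"] == baseline]
            .set_index("subject_id")[value_cols])
    rows = []
    for stage in stage_values["stage"].unique():
        if stage == baseline:
            continue
        cur = (stage_values[stage_values["stage"] == stage]
               .set_index("subject_id")[value_cols])
        relcur = (rel[rel["stage"] == stage]
                  .set_index("subject_id")[value_cols])
        common = cur.index.intersection(base.index)
        for col in value_cols:
            paired = pd.DataFrame({
                "x": cur.loc[common, col], "b": base.loc[common, col],
            }).dropna()
            r = relcur.loc[paired.index, col].dropna()
            wres = wilcoxon_vs_baseline(paired["x"], paired["b"])
            rows.append({
                "parameter": col, "stage": stage,
                "median_rel": float(r.median()),
                "q25": float(r.quantile(0.25)), "q75": float(r.quantile(0.75)),
                "p_value": wres.p_value, "n": len(paired),
                "degenerate": wres.degenerate,
            })
    return pd.DataFrame(rows)
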