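"""Grey-zone ROC diagnostics for a scalar marker against a binary outcome.

Beyond the point ROC curve and its trapezoidal AUC, the grey-zone approach
characterises the *uncertainty of the optimal cutoff*: the Youden-optimal
cutoff (maximising J = sensitivity + specificity - 1) is recomputed on
bootstrap resamples of the observations, and the grey zone is the 95%
percentile interval of that cutoff distribution. Marker values inside the
grey zone can neither rule the condition in nor out; values below the lower
bound rule it out and values above the upper bound rule it in.

:class:`GreyZoneAnalysis` is the model-style entry point:

>>> res = GreyZoneAnalysis(scores, labels).fit(n_boot=1000, random_state=7)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .errors import EvaluationError

__all__ = [
    "RocCurve",
    "GreyZoneResult",
    "roc_auc",
    "youden_best_cutoff",
    "bootstrap_auc_ci",
    "grey_zone",
    "GreyZoneAnalysis",
    "GreyZoneResults",
]


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise EvaluationError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite")
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise EvaluationError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present")
    return s, y


@dataclass(frozen=True)
class RocCurve:
    """ROC curve: thresholds with sensitivity/specificity, plus AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC (higher score = more positive).

    The trapezoidal AUC equals the Mann-Whitney rank statistic
    (concordant pairs + half ties) / (n_pos * n_neg).
    """
    s, y = _validate(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return RocCurve(
        thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
        auc=float(roc_auc_score(y, s)),
    )


def _scan(s: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """One sorted pass: (rank-statistic AUC, best Youden cutoff, best J).

    Candidate cutoffs are the midpoints between adjacent unique scores plus
    the two infinite extremes; classification is score >= cutoff ->
    positive; ties in J break toward the smaller cutoff. The AUC is the
    Mann-Whitney statistic with ties counted half.
    """
    u, inverse = np.unique(s, return_inverse=True)
    pos_hist = np.bincount(inverse[y == 1], minlength=u.size)
    neg_hist = np.bincount(inverse[y == 0], minlength=u.size)
    n_pos, n_neg = int(pos_hist.sum()), int(neg_hist.sum())
    cum_pos = np.cumsum(pos_hist)   # positives with score <= u[k]
    cum_neg = np.cumsum(neg_hist)
    auc = float(
        np.sum(pos_hist * (cum_neg - neg_hist + 0.5 * neg_hist)) / (n_pos * n_neg))
    # candidates: -inf, midpoints between adjacent unique scores, +inf
    cand = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]))
    sens = np.concatenate(([n_pos], n_pos - cum_pos[:-1], [0])) / n_pos
    spec = np.concatenate(([0], cum_neg[:-1], [n_neg])) / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (smallest) maximiser
    return auc, float(cand[best]), float(j[best])


def youden_best_cutoff(scores, labels, return_j: bool = False):
    """Cutoff maximising the Youden index J = sens + spec - 1.

    Candidates are the midpoints between adjacent unique scores plus the
    two infinite extremes; classification is score >= cutoff -> positive;
    ties in J break toward the smaller cutoff.
    """
    s, y = _validate(scores, labels)
    _, cut, j = _scan(s, y)
    if return_j:
        return cut, j
    return cut


def _bootstrap_indices(n: int, rng: np.random.Generator,
                       y: np.ndarray, stratified: bool) -> np.ndarray:
    if not stratified:
        return rng.integers(0, n, size=n)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    return np.concatenate([
        rng.choice(idx_pos, size=idx_pos.size, replace=True),
        rng.choice(idx_neg, size=idx_neg.size, replace=True),
    ])


def bootstrap_auc_ci(scores, labels, n_boot: int = 1000, seed=None,
                     stratified: bool = False) -> tuple[float, float, float]:
    """Bootstrap mean AUC with percentile 95% CI over observation resamples."""
    s, y = _validate(scores, labels)
    if n_boot < 2:
        raise EvaluationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_boot):
        idx = _bootstrap_indices(len(s), rng, y, stratified)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        aucs.append(roc_auc_score(yb, s[idx]))
    if not aucs:
        raise EvaluationError("every bootstrap replicate was single-class")
    aucs = np.asarray(aucs)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.mean()), float(lo), float(hi)


@dataclass(frozen=True)
class GreyZoneResult:
    """Bootstrap grey-zone summary for one marker."""

    auc_point: float
    auc_mean: float
    auc_ci_95: tuple[float, float]
    best_cutoff_mean: float
    cutoff_ci_95: tuple[float, float]
    n_bootstrap: int
    n_degenerate: int = 0  # replicates skipped (single-class / infinite cutoff)

    @property
    def grey_zone(self) -> tuple[float, float]:
        return self.cutoff_ci_95


def grey_zone(scores, labels, n_boot: int = 1000, seed=None,
              stratified: bool = False) -> GreyZoneResult:
    """AUC CI and Youden-cutoff grey zone from one bootstrap pass.

    On each of ``n_boot`` resamples both the AUC and the Youden-optimal
    cutoff are recomputed; the grey zone is the percentile 95% interval of
    the cutoff distribution. Replicates that are single-class or whose
    optimal cutoff is non-finite are skipped and counted.
    """
    s, y = _validate(scores, labels)
    if n_boot < 2:
        raise EvaluationError("n_boot must be >= 2")
    point = roc_auc(s, y).auc
    rng = np.random.default_rng(seed)
    aucs, cutoffs, degenerate = [], [], 0
    for _ in range(n_boot):
        idx = _bootstrap_indices(len(s), rng, y, stratified)
        yb, sb = y[idx], s[idx]
        if yb.min() == yb.max():
            degenerate += 1
            continue
        auc_b, cut, _ = _scan(sb, yb)
        if not np.isfinite(cut):
            degenerate += 1
            continue
        aucs.append(auc_b)
        cutoffs.append(cut)
    if not cutoffs:
        raise EvaluationError("no usable bootstrap replicate")
    aucs, cutoffs = np.asarray(aucs), np.asarray(cutoffs)
    return GreyZoneResult(
        auc_point=float(point),
        auc_mean=float(aucs.mean()),
        auc_ci_95=tuple(np.percentile(aucs, [2.5, 97.5])),
        best_cutoff_mean=float(cutoffs.mean()),
        cutoff_ci_95=tuple(np.percentile(cutoffs, [2.5, 97.5])),
        n_bootstrap=n_boot,
        n_degenerate=degenerate,
    )


class GreyZoneAnalysis:
    """Grey-zone diagnostic evaluation of one marker.

    Parameters
    ----------
    scores, labels : array-like
        Marker values and binary outcomes.
    orientation : {"auto", "greater", "less"}
        "greater": larger values indicate the positive class; "less": the
        marker is flipped; "auto" (default) picks the direction whose AUC
        is >= 0.5 and records it.
    name : str
        Marker name used in summaries.
    """

    def __init__(self, scores, labels, orientation: str = "auto",
                 name: str = "marker"):
        self.scores, self.labels = _validate(scores, labels)
        if orientation not in ("auto", "greater", "less"):
            raise EvaluationError(f"unknown orientation {orientation!r}")
        self.name = name
        if orientation == "auto":
            orientation = ("greater"
                           if roc_auc_score(self.labels, self.scores) >= 0.5
                           else "less")
        self.orientation = orientation

    def _oriented(self) -> np.ndarray:
        return self.scores if self.orientation == "greater" else -self.scores

    def fit(self, n_boot: int = 1000, random_state=None,
            stratified: bool = False) -> "GreyZoneResults":
        res = grey_zone(self._oriented(), self.labels, n_boot=n_boot,
                        seed=random_state, stratified=stratified)
        curve = roc_auc(self._oriented(), self.labels)
        return GreyZoneResults(self, res, curve)


class GreyZoneResults:
    """Fitted grey-zone analysis: AUC CI, cutoff distribution, grey zone.

    Cutoffs are reported on the *oriented* score scale (sign-flipped when
    orientation is "less").
    """

    def __init__(self, model: GreyZoneAnalysis, result: GreyZoneResult,
                 curve: RocCurve):
        self.model = model
        self.result = result
        self.curve = curve

    @property
    def auc(self) -> float:
        return self.result.auc_point

    @property
    def grey_zone(self) -> tuple[float, float]:
        return self.result.grey_zone

    def to_dict(self) -> dict:
        r = self.result
        return {
            "marker": self.model.name,
            "orientation": self.model.orientation,
            "auc": r.auc_point,
            "auc_mean": r.auc_mean,
            "auc_ci_95": list(r.auc_ci_95),
            "best_cutoff_mean": r.best_cutoff_mean,
            "grey_zone": list(r.cutoff_ci_95),
            "n_bootstrap": r.n_bootstrap,
            "n_degenerate": r.n_degenerate,
        }

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Grey-zone ROC analysis: {self.model.name}",
            f"  orientation            {self.model.orientation}",
            f"  AUC (point)            {r.auc_point:.3f}",
            f"  AUC bootstrap mean     {r.auc_mean:.3f} "
            f"(95% CI {r.auc_ci_95[0]:.3f} to {r.auc_ci_95[1]:.3f})",
            f"  best cutoff (mean)     {r.best_cutoff_mean:.4g}",
            f"  grey zone              {r.cutoff_ci_95[0]:.4g} to {r.cutoff_ci_95[1]:.4g}",
            f"  bootstrap replicates   {r.n_bootstrap} ({r.n_degenerate} degenerate)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """ROC curve with the grey zone marked on the threshold axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1.0 - self.curve.specificity, self.curve.sensitivity,
                drawstyle="steps-post", label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.model.name} (grey zone "
                     f"{self.grey_zone[0]:.3g} to {self.grey_zone[1]:.3g})")
        ax.legend(loc="lower right")
        return ax
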