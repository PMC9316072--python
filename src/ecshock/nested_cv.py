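"""Subject-grouped leave-two-out nested cross-validation.

The outer loop holds out two whole subjects per repetition (their relational
observations form the test set) so that no within-subject information leaks
between training and testing; the inner loop is 10-fold cross-validation at
the observation level, used for feature selection and hyperparameter grid
search. Everything fitted — the feature scaler, the selector, the grid —
sees training subjects only.

Five classifier families are supported (KNN, Naive Bayes with optional
per-feature Gaussian-KDE class densities, Random Forest, linear and radial
SVM), each with its grid and its default feature-selection route: none for
KNN, recursive elimination for NB, the gain-ratio filter for radial SVM and
the union of three entropy filters (information gain, gain ratio,
symmetrical uncertainty) for linear SVM and RF. If the inner search picks a
value on the edge of a grid axis, the axis is extended by its step pattern
and the search rerun (at most twice per axis).

Per repetition the held-out AUC of the fitted model is recorded next to the
AUCs of scalar vital-sign markers on the *same* held-out observations;
distributions over the repetitions are compared by a two-sided
Mann-Whitney test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError, EvaluationError, TrainingError
from .features import FeatureScaler, feature_columns
from .naive_bayes import KernelNaiveBayes
from .protocol import ProtocolDefinition, default_protocol
from .relational import build_relational

__all__ = [
    "ModelSpec",
    "OuterSplit",
    "CvResult",
    "default_model_specs",
    "make_ltocv_splits",
    "entropy_filters",
    "select_features",
    "forward_wrapper_select",
    "grid_search",
    "expand_grid_if_edge",
    "run_nested_cv",
    "compare_auc",
    "NestedCVExperiment",
    "NestedCVResults",
]

_ALGORITHMS = ("knn", "nb", "rf", "svmlin", "svmrad")
_GRID_AXES = {
    "knn": {"k"},
    "nb": {"adjust", "kernel", "fL"},
    "rf": {"mtry"},
    "svmlin": {"cost"},
    "svmrad": {"sigma", "cost"},
}
_SELECTION_METHODS = (
    "all", "recursive-elimination", "gain-ratio-filter",
    "entropy-filter-union", "forward-wrapper",
)


@dataclass
class ModelSpec:
    """One classifier family with its grid and feature-selection route."""

    algorithm: str
    grid: dict[str, list]
    selection: str = "all"
    inner_folds: int = 10
    name: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if set(self.grid) != _GRID_AXES[self.algorithm]:
            raise ConfigurationError(
                f"{self.algorithm}: grid axes {sorted(self.grid)} do not match "
                f"required {sorted(_GRID_AXES[self.algorithm])}")
        if self.selection not in _SELECTION_METHODS:
            raise ConfigurationError(f"unknown selection {self.selection!r}")
        if not all(len(v) > 0 for v in self.grid.values()):
            raise ConfigurationError("empty grid axis")
        if self.name is None:
            self.name = self.algorithm


def default_model_specs(n_features: int = 119) -> list[ModelSpec]:
    """The five families with their final grids and default selectors.

    Negative Naive-Bayes bandwidth/smoothing grid values are clamped to
    valid (non-negative, bandwidth > 0) settings. The KNN neighbour grid is
    capped at the number of offered features following the published
    convention of tying its upper end to the feature count.
    """
    k_max = max(3, n_features if n_features % 2 == 1 else n_features - 1)
    return [
        ModelSpec("knn", {"k": list(range(1, k_max + 1, 2))}, "all"),
        ModelSpec("nb", {"adjust": [0.5, 1.0, 1.5],
                         "kernel": [False, True],
                         "fL": [0.0, 0.5, 1.0]},
                  "recursive-elimination"),
        ModelSpec("svmrad", {"sigma": [2.0**e for e in (-10, -9, -8, -7, -6, -4)],
                             "cost": [0.1, 0.2, 0.4, 0.6, 0.8, 1, 2, 4, 8, 16]},
                  "gain-ratio-filter"),
        ModelSpec("svmlin", {"cost": [1e-4, 1e-3, 1e-2, 0.1, 0.2, 0.4, 0.8, 1, 2, 4]},
                  "entropy-filter-union"),
        ModelSpec("rf", {"mtry": list(range(1, 16))}, "entropy-filter-union"),
    ]


def _build_estimator(algorithm: str, params: dict, n_features: int, seed: int):
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=int(params["k"]))
    if algorithm == "nb":
        return KernelNaiveBayes(kernel=bool(params["kernel"]),
                                adjust=float(params["adjust"]),
                                laplace=float(params["fL"]))
    if algorithm == "rf":
        mtry = int(np.clip(params["mtry"], 1, n_features))
        return RandomForestClassifier(n_estimators=100, max_features=mtry,
                                      random_state=seed)
    if algorithm == "svmlin":
        return SVC(kernel="linear", C=float(params["cost"]), probability=False)
    if algorithm == "svmrad":
        return SVC(kernel="rbf", C=float(params["cost"]),
                   gamma=float(params["sigma"]), probability=False)
    raise ConfigurationError(algorithm)


def _decision_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


# ---------------------------------------------------------------------------
# outer splits


@dataclass(frozen=True)
class OuterSplit:
    repetition: int
    test_subjects: tuple[str, str]
    train_subjects: tuple[str, ...]


def make_ltocv_splits(subject_ids, n_rep: int = 29, seed=None) -> list[OuterSplit]:
    """Leave-two-(subjects)-out splits, pairs drawn without repetition.

    Pairs are sampled uniformly from all C(n, 2) subject pairs without
    duplicates while possible; if more repetitions than distinct pairs are
    requested, the pair pool is reshuffled and reused.
    """
    ids = sorted(set(map(str, subject_ids)))
    if len(ids) < 4:
        raise ConfigurationError("need at least 4 subjects for LTOCV")
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(ids, 2))
    chosen: list[tuple[str, str]] = []
    while len(chosen) < n_rep:
        perm = [pairs[i] for i in rng.permutation(len(pairs))]
        chosen.extend(perm[: n_rep - len(chosen)])
    return [
        OuterSplit(rep + 1, pair, tuple(s for s in ids if s not in pair))
        for rep, pair in enumerate(chosen[:n_rep])
    ]


# ---------------------------------------------------------------------------
# feature selection


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(x: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-frequency binning; collapsed edges merge bins deterministically."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def entropy_filters(X, y, n_bins: int = 5) -> pd.DataFrame:
    """Information gain, gain ratio and symmetrical uncertainty per feature.

    Continuous features are discretized into equal-frequency bins. All
    three scores are non-negative; constant features score 0 on all three.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("single-class labels: selection undefined")
    h_y = _entropy(np.bincount(y))
    rows = []
    for j in range(X.shape[1]):
        b = _discretize(X[:, j], n_bins)
        n_levels = int(b.max()) + 1
        h_x = _entropy(np.bincount(b))
        if h_x == 0.0:
            rows.append({"info_gain": 0.0, "gain_ratio": 0.0, "sym_uncert": 0.0})
            continue
        h_y_given_x = 0.0
        for level in range(n_levels):
            mask = b == level
            if mask.any():
                h_y_given_x += mask.mean() * _entropy(np.bincount(y[mask]))
        ig = max(0.0, h_y - h_y_given_x)
        rows.append({
            "info_gain": ig,
            "gain_ratio": ig / h_x,
            "sym_uncert": 2.0 * ig / (h_x + h_y) if (h_x + h_y) > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def _inner_cv_auc(spec: ModelSpec, params: dict, X: np.ndarray, y: np.ndarray,
                  seed: int) -> float:
    n_splits = min(spec.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise TrainingError("too few observations per class for inner CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = _build_estimator(spec.algorithm, params, X.shape[1], seed)
        est.fit(X[tr], y[tr])
        if len(np.unique(y[te])) < 2:
            continue
        aucs.append(roc_auc_score(y[te], _decision_scores(est, X[te])))
    if not aucs:
        raise TrainingError("no inner fold with both classes")
    return float(np.mean(aucs))


def _representative_params(grid: dict) -> dict:
    return {axis: values[len(values) // 2] for axis, values in grid.items()}


def forward_wrapper_select(spec: ModelSpec, X, y, seed=None,
                           tol: float = 1e-3, max_features=None) -> list[int]:
    """Greedy forward wrapper: add the feature that best improves inner-CV
    AUC; stop when no candidate improves by more than ``tol``.

    Evaluation uses a fixed mid-grid hyperparameter setting (the grid
    search proper runs afterwards on the selected subset). If even the
    first feature fails to beat chance the best single feature is kept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[1] < 2:
        raise EvaluationError("need >= 2 candidate features")
    params = _representative_params(spec.grid)
    limit = max_features or X.shape[1]
    selected: list[int] = []
    best_auc = 0.5
    remaining = list(range(X.shape[1]))
    first_round_best: tuple[float, int] | None = None
    while remaining and len(selected) < limit:
        scores = []
        for j in remaining:
            cols = selected + [j]
            scores.append(_inner_cv_auc(spec, params, X[:, cols], y, seed or 0))
        k = int(np.argmax(scores))
        if not selected:
            first_round_best = (scores[k], remaining[k])
        if scores[k] <= best_auc + tol:
            break
        best_auc = scores[k]
        selected.append(remaining.pop(k))
    if not selected and first_round_best is not None:
        # guard: never return an empty model
        selected = [first_round_best[1]]
    return selected


def select_features(spec: ModelSpec, X, y, seed=None) -> list[int]:
    """Feature indices chosen by the spec's selection route."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    p = X.shape[1]
    if spec.selection == "all":
        return list(range(p))
    if spec.selection == "forward-wrapper":
        return forward_wrapper_select(spec, X, y, seed=seed)
    scores = entropy_filters(X, y)
    if spec.selection == "gain-ratio-filter":
        keep = np.flatnonzero(scores["gain_ratio"].to_numpy() > 0)
    elif spec.selection == "entropy-filter-union":
        keep = np.flatnonzero((scores.to_numpy() > 0).any(axis=1))
    elif spec.selection == "recursive-elimination":
        # rank by symmetrical uncertainty, evaluate a shrinking size ladder
        # by inner-CV AUC, keep the best-performing subset size
        order = np.argsort(-scores["sym_uncert"].to_numpy(), kind="stable")
        sizes = sorted({max(1, p // (2**i)) for i in range(0, 8)} | {p})
        params = _representative_params(spec.grid)
        best = (-np.inf, p)
        for size in sizes:
            auc = _inner_cv_auc(spec, params, X[:, order[:size]], y, seed or 0)
            if auc > best[0]:
                best = (auc, size)
        keep = order[: best[1]]
    else:  # pragma: no cover
        raise ConfigurationError(spec.selection)
    if keep.size == 0:
        keep = np.array([int(np.argmax(scores["sym_uncert"].to_numpy()))])
    return sorted(int(i) for i in keep)


# ---------------------------------------------------------------------------
# grid search


def _grid_points(grid: dict) -> list[dict]:
    # ascending order per axis so the first maximiser is the least complex
    axes = sorted(grid)
    values = [sorted(grid[a], key=lambda v: (isinstance(v, bool), v)) for a in axes]
    return [dict(zip(axes, combo)) for combo in itertools.product(*values)]


def grid_search(spec: ModelSpec, X, y, seed=None) -> tuple[dict, float]:
    """Exhaustive inner-CV grid search; returns (best params, best AUC).

    Ties break toward the smaller value on every numeric axis (ascending
    scan order keeps the first maximiser).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    best: tuple[float, dict] | None = None
    errors = []
    for params in _grid_points(spec.grid):
        try:
            auc = _inner_cv_auc(spec, params, X, y, seed or 0)
        except (TrainingError, ValueError) as exc:
            errors.append((params, exc))
            continue
        if best is None or auc > best[0]:
            best = (auc, params)
    if best is None:
        raise TrainingError(f"every grid setting failed: {errors[:3]}")
    return best[1], best[0]


def expand_grid_if_edge(spec: ModelSpec, chosen: dict,
                        expansions: dict | None = None,
                        max_expansions: int = 2) -> tuple[dict, bool, dict]:
    """Extend any numeric axis whose chosen value sits on the grid edge.

    The axis is extended past the edge following its step pattern
    (geometric when consecutive ratios are constant, arithmetic otherwise),
    at most ``max_expansions`` times per axis per direction. Returns the
    possibly enlarged grid, a rerun flag, and the updated expansion log.
    """
    expansions = dict(expansions or {})
    grid = {a: list(v) for a, v in spec.grid.items()}
    rerun = False
    for axis, values in grid.items():
        vals = sorted(v for v in values if isinstance(v, (int, float))
                      and not isinstance(v, bool))
        if len(vals) < 2 or not isinstance(chosen[axis], (int, float)) \
                or isinstance(chosen[axis], bool):
            continue
        ratios = np.array(vals[1:]) / np.array(vals[:-1]) \
            if all(v > 0 for v in vals) else None
        geometric = ratios is not None and np.allclose(ratios, ratios[0])
        for side, edge in (("low", vals[0]), ("high", vals[-1])):
            if chosen[axis] != edge:
                continue
            key = (axis, side)
            if expansions.get(key, 0) >= max_expansions:
                continue
            if geometric:
                step = ratios[0]
                new = edge / step if side == "low" else edge * step
            else:
                step = (vals[1] - vals[0]) if side == "low" else (vals[-1] - vals[-2])
                new = edge - step if side == "low" else edge + step
            if new <= 0 and all(v > 0 for v in vals):
                continue  # never extend a positive axis into <= 0
            if isinstance(edge, int) and float(new).is_integer():
                new = int(new)
            grid[axis] = sorted(set(values) | {new})
            expansions[key] = expansions.get(key, 0) + 1
            rerun = True
    return grid, rerun, expansions


# ---------------------------------------------------------------------------
# the nested loop


@dataclass
class CvResult:
    """Per-model outcome of the outer loop."""

    algorithm: str
    aucs: list[float]                      # one per repetition, NaN if undefined
    selected_features: list[list[str]]
    chosen_params: list[dict]
    expansion_events: list[dict]

    @property
    def auc_array(self) -> np.ndarray:
        return np.asarray(self.aucs, dtype=float)


def _marker_auc(train_scores, train_labels, test_scores, test_labels) -> float:
    """Held-out AUC of a scalar marker, oriented on the training data."""
    if len(np.unique(test_labels)) < 2 or len(np.unique(train_labels)) < 2:
        return float("nan")
    flip = roc_auc_score(train_labels, train_scores) < 0.5
    s = -np.asarray(test_scores) if flip else np.asarray(test_scores)
    return float(roc_auc_score(test_labels, s))


def run_nested_cv(models: list[ModelSpec],
                  features: pd.DataFrame,
                  feature_cols=None,
                  marker_cols=("hr", "sbp", "dbp", "map"),
                  protocol: ProtocolDefinition | None = None,
                  n_rep: int = 29,
                  seed=None,
                  permute_labels_within_subject: bool = False,
                  ) -> tuple[dict[str, CvResult], pd.DataFrame]:
    """The full nested loop on a raw (unstandardized) feature table.

    For every outer repetition: fit the z-score scaler on training
    subjects' windows, build relational observations for train and test
    separately, run the model's feature selection and grid search (with
    edge expansion) on the training observations via inner 10-fold CV,
    refit on all training observations and score the held-out subjects.

    ``marker_cols`` are raw stage-level columns (vital signs; ``hr`` uses
    the window-mean heart rate) whose relational differences are evaluated
    as scalar comparators on the same held-out observations.

    Returns (results per model, marker AUC table with one row per
    repetition). ``permute_labels_within_subject`` shuffles training and
    test labels within each subject — the permutation null.
    """
    protocol = protocol or default_protocol()
    if feature_cols is None:
        feature_cols = [c for c in feature_columns() if c in features.columns]
    # markers are differenced on the raw scale and kept apart from the
    # z-scored model features under a marker_ prefix
    marker_src = {m: (f"{m}_mean" if m not in features.columns else m)
                  for m in marker_cols}
    marker_map = {m: f"marker_{m}" for m in marker_cols}
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    split_seed, work_seed = ss.spawn(2)
    splits = make_ltocv_splits(features["subject_id"].unique(),
                               n_rep=n_rep, seed=split_seed)
    work_rng = np.random.default_rng(work_seed)

    results = {m.name: CvResult(m.algorithm, [], [], [], []) for m in models}
    marker_rows = []
    for split in splits:
        rep_seed = int(work_rng.integers(0, 2**31 - 1))
        train_tab = features[features["subject_id"].isin(split.train_subjects)]
        test_tab = features[features["subject_id"].isin(split.test_subjects)]

        scaler = FeatureScaler().fit(train_tab, feature_cols)
        scaled_cols = scaler.columns

        def _relational(tab):
            z = scaler.transform(tab)
            base = tab[["subject_id", "stage", "sv_tte_ml"]].reset_index(drop=True)
            for m, src in marker_src.items():
                base[marker_map[m]] = tab[src].to_numpy()
            rel = build_relational(
                pd.concat([base, z.reset_index(drop=True)], axis=1),
                feature_cols=scaled_cols,
                marker_cols=list(marker_map.values()),
                protocol=protocol)
            return rel[rel["valid"]].reset_index(drop=True)

        train_rel = _relational(train_tab)
        test_rel = _relational(test_tab)
        if permute_labels_within_subject:
            perm_rng = np.random.default_rng(rep_seed)
            for rel in (train_rel, test_rel):
                for _, idx in rel.groupby("subject_id").groups.items():
                    vals = rel.loc[idx, "label"].to_numpy()
                    rel.loc[idx, "label"] = perm_rng.permutation(vals)

        X_train = train_rel[scaled_cols].to_numpy(float)
        y_train = train_rel["label"].to_numpy(int)
        X_test = test_rel[scaled_cols].to_numpy(float)
        y_test = test_rel["label"].to_numpy(int)

        for marker, col in marker_map.items():
            marker_rows.append({
                "repetition": split.repetition, "marker": marker,
                "auc": _marker_auc(train_rel[col], y_train,
                                   test_rel[col], y_test),
            })

        for model in models:
            res = results[model.name]
            if len(np.unique(y_train)) < 2:
                res.aucs.append(float("nan"))
                res.selected_features.append([])
                res.chosen_params.append({})
                continue
            sel = select_features(model, X_train, y_train, seed=rep_seed)
            spec = ModelSpec(model.algorithm, {a: list(v) for a, v in model.grid.items()},
                             model.selection, model.inner_folds, model.name)
            expansions: dict = {}
            while True:
                chosen, inner_auc = grid_search(spec, X_train[:, sel], y_train,
                                                seed=rep_seed)
                new_grid, rerun, expansions = expand_grid_if_edge(
                    spec, chosen, expansions)
                if not rerun:
                    break
                res.expansion_events.append({
                    "repetition": split.repetition, "chosen": dict(chosen),
                    "grid": {a: list(v) for a, v in new_grid.items()}})
                spec = ModelSpec(spec.algorithm, new_grid, spec.selection,
                                 spec.inner_folds, spec.name)
            est = _build_estimator(model.algorithm, chosen, len(sel), rep_seed)
            est.fit(X_train[:, sel], y_train)
            if len(np.unique(y_test)) < 2:
                auc = float("nan")
            else:
                auc = float(roc_auc_score(y_test,
                                          _decision_scores(est, X_test[:, sel])))
            res.aucs.append(auc)
            res.selected_features.append([scaled_cols[i] for i in sel])
            res.chosen_params.append(chosen)

    marker_aucs = pd.DataFrame(marker_rows)
    return results, marker_aucs


def compare_auc(model_aucs, marker_aucs) -> float:
    """Two-sided Mann-Whitney p-value between two AUC distributions."""
    a = np.asarray(model_aucs, dtype=float)
    b = np.asarray(marker_aucs, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise EvaluationError("need >= 2 AUC values per group")
    if np.array_equal(a, b) and np.unique(a).size == 1:
        return 1.0
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# model-style front end


class NestedCVExperiment:
    """Nested-CV evaluation of classifier families on a raw feature table.

    Parameters
    ----------
    features : DataFrame
        Raw per-(subject, stage) feature table from
        :func:`ecshock.features.build_feature_table`.
    models : list of ModelSpec, optional
        Defaults to the five standard families.
    protocol : ProtocolDefinition, optional
    marker_cols : columns evaluated as scalar comparators.
    """

    def __init__(self, features: pd.DataFrame, models=None,
                 protocol: ProtocolDefinition | None = None,
                 marker_cols=("hr", "sbp", "dbp", "map")):
        self.features = features
        n_feat = len([c for c in feature_columns() if c in features.columns])
        self.models = models if models is not None else default_model_specs(n_feat)
        self.protocol = protocol or default_protocol()
        self.marker_cols = tuple(marker_cols)

    def fit(self, n_rep: int = 29, seed=None,
            permute_labels_within_subject: bool = False) -> "NestedCVResults":
        results, marker_aucs = run_nested_cv(
            self.models, self.features, protocol=self.protocol,
            marker_cols=self.marker_cols, n_rep=n_rep, seed=seed,
            permute_labels_within_subject=permute_labels_within_subject)
        return NestedCVResults(self, results, marker_aucs, n_rep=n_rep, seed=seed)


class NestedCVResults:
    """Held-out AUC distributions per model and marker, with comparisons."""

    def __init__(self, experiment: NestedCVExperiment,
                 results: dict[str, CvResult], marker_aucs: pd.DataFrame,
                 n_rep: int, seed):
        self.experiment = experiment
        self.results = results
        self.marker_aucs = marker_aucs
        self.n_rep = n_rep
        self.seed = seed

    def auc_table(self) -> pd.DataFrame:
        """Long table: repetition, name, kind (model/marker), auc."""
        rows = []
        for name, res in self.results.items():
            for rep, auc in enumerate(res.aucs, start=1):
                rows.append({"repetition": rep, "name": name,
                             "kind": "model", "auc": auc})
        for _, r in self.marker_aucs.iterrows():
            rows.append({"repetition": int(r["repetition"]), "name": r["marker"],
                         "kind": "marker", "auc": r["auc"]})
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        tab = self.auc_table().dropna(subset=["auc"])
        agg = tab.groupby(["kind", "name"])["auc"].agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n="count").reset_index()
        return agg.sort_values(["kind", "median"], ascending=[True, False])

    def compare(self, model_name: str, marker: str) -> float:
        model = self.results[model_name].auc_array
        mk = self.marker_aucs.loc[self.marker_aucs["marker"] == marker, "auc"]
        return compare_auc(model, mk.to_numpy())

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for name in self.results:
            for marker in self.experiment.marker_cols:
                rows.append({"model": name, "marker": marker,
                             "p_value": self.compare(name, marker)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Nested leave-two-subjects-out CV ({self.n_rep} repetitions)",
                 "", "Held-out AUC (median [q25, q75], n valid):"]
        for _, r in self.summary_frame().iterrows():
            lines.append(f"  {r['kind']:<7}{r['name']:<8}"
                         f"{r['median']:.3f} [{r['q25']:.3f}, {r['q75']:.3f}]"
                         f"  n={int(r['n'])}")
        comp = self.comparison_table()
        if len(comp):
            lines += ["", "Model vs marker (Mann-Whitney, two-sided):"]
            for _, r in comp.iterrows():
                lines.append(f"  {r['model']:<8}vs {r['marker']:<5}"
                             f"p = {r['p_value']:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Boxplots of the per-repetition AUC distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        tab = self.auc_table().dropna(subset=["auc"])
        names = list(dict.fromkeys(tab["name"]))
        data = [tab.loc[tab["name"] == n, "auc"] for n in names]
        ax.boxplot(data, tick_labels=names)
        ax.set_ylabel("held-out AUC")
        ax.axhline(0.5, ls="--", c="grey", lw=0.8)
        return ax
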