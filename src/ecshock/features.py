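"""Analysis-window extraction and descriptive-statistic features.

Each (subject, stage) contributes one analysis window: the last
``window_length`` seconds of the stage, which by protocol construction never
overlaps the excluded settling interval at the stage head. Seven descriptive
statistics (mean, median, sd, var, skew, kurt, iqr) are computed per EC
channel per window, giving the ``<channel>_<statistic>`` feature grid, and
features are z-scored with a scaler that can be fitted on a reference
(training) set and applied elsewhere — the standard guard against
train/test leakage.

Conventions: sd and var use the n-1 (sample) denominator; skewness is the
moment coefficient g1 and kurtosis the excess coefficient g2 (normal = 0),
both set to 0 for zero-variance windows; IQR uses linear-interpolation
quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import EC_PARAMETERS, VITAL_SIGNS
from .errors import DataError, SchemaError
from .protocol import ProtocolDefinition
from .simulate import CohortDataset

__all__ = [
    "STATISTICS",
    "DEFAULT_FEATURE_PARAMETERS",
    "AnalysisWindow",
    "extract_windows",
    "compute_descriptors",
    "build_feature_table",
    "FeatureScaler",
    "feature_columns",
]

STATISTICS = ("mean", "median", "sd", "var", "skew", "kurt", "iqr")

#: channels entering the feature grid by default; the ccc development
#: counter is excluded (it encodes elapsed beats, not physiology)
DEFAULT_FEATURE_PARAMETERS = tuple(p for p in EC_PARAMETERS if p != "ccc")

MIN_WINDOW_BEATS = 10


@dataclass
class AnalysisWindow:
    """Beats of one subject-stage analysis window."""

    subject_id: str
    stage: str
    beats: pd.DataFrame
    degenerate: bool = False


def extract_windows(cohort: CohortDataset,
                    protocol: ProtocolDefinition | None = None) -> list[AnalysisWindow]:
    """One window per (subject, stage) present in the beat table.

    Windows with fewer than ``MIN_WINDOW_BEATS`` beats are flagged
    degenerate and excluded from feature computation downstream.
    """
    protocol = protocol or cohort.protocol
    windows = []
    for (subject_id, stage), grp in cohort.beats.groupby(
            ["subject_id", "stage"], sort=False):
        lo, hi = protocol.window_bounds(stage)
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{subject_id}/{stage}: beat times not strictly increasing")
        sel = grp[(t >= lo) & (t < hi)]
        windows.append(AnalysisWindow(
            subject_id=subject_id, stage=stage, beats=sel,
            degenerate=len(sel) < MIN_WINDOW_BEATS,
        ))
    order = {lab: i for i, lab in enumerate(protocol.labels)}
    windows.sort(key=lambda w: (w.subject_id, order.get(w.stage, len(order))))
    return windows


def _descriptors(x: np.ndarray) -> dict[str, float]:
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": sd,
        "var": sd * sd,
        "skew": skew,
        "kurt": kurt,
        "iqr": float(q75 - q25),
    }


def compute_descriptors(window: AnalysisWindow,
                        parameters=DEFAULT_FEATURE_PARAMETERS) -> dict[str, float]:
    """The 7-statistic descriptor grid of one window, as a flat dict."""
    if window.degenerate:
        raise DataError(
            f"{window.subject_id}/{window.stage}: degenerate window "
            f"({len(window.beats)} beats)")
    out: dict[str, float] = {}
    for param in parameters:
        stats = _descriptors(window.beats[param].to_numpy(dtype=float))
        for stat in STATISTICS:
            out[f"{param}_{stat}"] = stats[stat]
    return out


def feature_columns(parameters=DEFAULT_FEATURE_PARAMETERS) -> list[str]:
    return [f"{p}_{s}" for p in parameters for s in STATISTICS]


def build_feature_table(cohort: CohortDataset,
                        protocol: ProtocolDefinition | None = None,
                        parameters=DEFAULT_FEATURE_PARAMETERS) -> pd.DataFrame:
    """Feature matrix: one row per non-degenerate (subject, stage) window.

    Columns are the ``<channel>_<statistic>`` grid plus the echo reference
    ``sv_tte_ml`` (NaN where the echo measurement is flagged missing) and
    the cuff vital signs — reference/marker columns, not model features.
    """
    protocol = protocol or cohort.protocol
    rows = []
    for window in extract_windows(cohort, protocol):
        if window.degenerate:
            continue
        rows.append({"subject_id": window.subject_id, "stage": window.stage,
                     **compute_descriptors(window, parameters)})
    table = pd.DataFrame(rows)

    echo = cohort.echo[["subject_id", "stage", "sv_tte_ml", "missing"]].copy()
    echo.loc[echo["missing"].astype(bool), "sv_tte_ml"] = np.nan
    table = table.merge(echo.drop(columns="missing"),
                        on=["subject_id", "stage"], how="left")
    table = table.merge(cohort.vitals[["subject_id", "stage", *VITAL_SIGNS]],
                        on=["subject_id", "stage"], how="left")
    return table


@dataclass
class FeatureScaler:
    """Per-feature z-scoring learned from a reference set.

    Zero-variance features in the reference set are recorded in
    ``dropped`` and removed consistently at transform time.
    """

    location: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    scale: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    dropped: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.location.index)

    def fit(self, table: pd.DataFrame, columns=None) -> "FeatureScaler":
        cols = list(columns) if columns is not None else list(table.columns)
        if len(table) < 2:
            raise DataError("need at least 2 rows to fit a scaler")
        mu = table[cols].mean()
        sd = table[cols].std(ddof=1)
        self.dropped = [c for c in cols if not np.isfinite(sd[c]) or sd[c] == 0.0]
        keep = [c for c in cols if c not in self.dropped]
        self.location, self.scale = mu[keep], sd[keep]
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise SchemaError(f"columns absent at transform time: {missing[:5]}")
        return (table[self.columns] - self.location) / self.scale

    def fit_transform(self, table: pd.DataFrame, columns=None) -> pd.DataFrame:
        return self.fit(table, columns).transform(table)
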