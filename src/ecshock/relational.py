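"""Relational observations: pair each timepoint with every earlier one.

To multiply the number of labelled samples obtainable from a small cohort,
every observed timepoint of a subject is related to each of its earlier
timepoints; the feature vector of the pair is the element-wise difference of
the (z-scored) window features (target minus reference), and the binary
label records whether the echo reference stroke volume fell by 20% or more
between the two timepoints. The baseline timepoint additionally enters once
on its own as an all-zero self-relation with a negative label, so a subject
with T observed timepoints contributes 1 + T(T-1)/2 observations.

Observations whose echo reference is missing at either endpoint are emitted
with ``valid=False`` and excluded from modelling (but kept for counts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .protocol import BASELINE, ProtocolDefinition, default_protocol

__all__ = [
    "label_observation",
    "count_relational",
    "build_relational",
    "DECREASE_THRESHOLD",
]

#: a relative SV-TTE decrease of 20% or more defines the positive class
DECREASE_THRESHOLD = 0.20


def label_observation(sv_ref: float, sv_target: float) -> int:
    """1 if the reference stroke volume fell by >= 20% from ref to target."""
    if sv_ref <= 0 or sv_target <= 0:
        raise DomainError("stroke volumes must be positive")
    return int(sv_target <= (1.0 - DECREASE_THRESHOLD) * sv_ref)


def count_relational(n_subjects: int, n_timepoints: int) -> int:
    """Number of relational observations for a fully observed cohort."""
    if n_subjects < 1 or n_timepoints < 1:
        raise DomainError("counts must be >= 1")
    t = n_timepoints
    return n_subjects * (1 + t * (t - 1) // 2)


def build_relational(features: pd.DataFrame,
                     feature_cols,
                     marker_cols=(),
                     protocol: ProtocolDefinition | None = None,
                     sv_col: str = "sv_tte_ml") -> pd.DataFrame:
    """Build the relational table from a per-(subject, stage) feature table.

    Parameters
    ----------
    features : DataFrame
        One row per (subject, stage); must contain ``subject_id``,
        ``stage``, the feature columns (already standardized), the marker
        columns (raw scalar markers such as vital signs, differenced the
        same way) and the echo reference column ``sv_col`` (NaN = missing).
    feature_cols, marker_cols : sequences of str
        Columns differenced into relational features / comparison markers.
    protocol : ProtocolDefinition
        Supplies the total stage order.

    Returns
    -------
    DataFrame with subject_id, ref_stage, target_stage, label, valid and
    the differenced feature/marker columns. The baseline self-relation is
    the zero vector with a negative label; its validity requires only the
    baseline echo measurement.
    """
    protocol = protocol or default_protocol()
    order = {lab: i for i, lab in enumerate(protocol.labels)}
    feature_cols = list(feature_cols)
    marker_cols = list(marker_cols)
    diff_cols = feature_cols + marker_cols

    if features.duplicated(["subject_id", "stage"]).any():
        raise DataError("duplicate (subject, stage) rows in feature table")
    unknown = set(features["stage"]) - set(order)
    if unknown:
        raise DataError(f"stages outside protocol order: {sorted(unknown)}")

    rows = []
    for subject_id, grp in features.groupby("subject_id", sort=True):
        grp = grp.sort_values("stage", key=lambda s: s.map(order))
        stages = grp["stage"].tolist()
        sv = grp[sv_col].to_numpy(dtype=float)
        vals = grp[diff_cols].to_numpy(dtype=float)
        for i, target in enumerate(stages):
            if target == BASELINE:
                # baseline singleton: self-relation, negative by construction
                rows.append({
                    "subject_id": subject_id, "ref_stage": target,
                    "target_stage": target, "label": 0,
                    "valid": bool(np.isfinite(sv[i])),
                    **dict.fromkeys(diff_cols, 0.0),
                })
            for j in range(i):
                valid = bool(np.isfinite(sv[j]) and np.isfinite(sv[i]))
                label = label_observation(sv[j], sv[i]) if valid else 0
                rows.append({
                    "subject_id": subject_id, "ref_stage": stages[j],
                    "target_stage": target, "label": label, "valid": valid,
                    **dict(zip(diff_cols, vals[i] - vals[j])),
                })
    return pd.DataFrame(rows)
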