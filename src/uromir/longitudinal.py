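"""Per-patient three-timepoint trend calls and cross-patient concordance.

A candidate marker that tracks tumour burden should fall after curative
surgery and rise again at recurrence if it is elevated in cancer
(``down_up``), or show the mirror image if it is reduced in cancer
(``up_down``).  Trend calls are made per patient and per miRNA from log2
expression at the pre-treatment, post-surgery and recurrence timepoints; a
call is *concordant* when the observed pattern matches the expectation for
the marker's cancer direction, and a marker is *consistent* when it is
concordant with the same pattern in every evaluated patient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TIMEPOINTS

PATTERNS = ("down_up", "up_down", "other")
_EXPECTED_PATTERN = {"up": "down_up", "down": "up_down"}


def call_trend(v_pre: float, v_post: float, v_rec: float, min_delta: float = 0.0) -> str:
    """Classify one three-timepoint trajectory.

    ``down_up``: drops from pre-treatment to post-surgery and rises again at
    recurrence, each move by at least ``min_delta`` log2 units; ``up_down``
    is the mirror; anything else is ``other``.  The default margin of zero
    counts any change, matching qualitative visual calls.
    """
    vals = (v_pre, v_post, v_rec)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError(f"trajectory values must be finite, got {vals}")
    if min_delta < 0:
        raise ValueError(f"min_delta must be >= 0, got {min_delta}")
    if v_post <= v_pre - min_delta and v_rec >= v_post + min_delta:
        return "down_up"
    if v_post >= v_pre + min_delta and v_rec <= v_post - min_delta:
        return "up_down"
    return "other"


def extract_trajectories(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Long table of (patient_id, feature_id, v_pre, v_post, v_rec).

    Every longitudinal patient must have exactly one sample at each of the
    three timepoints present in the expression matrix; incomplete series are
    rejected rather than imputed.
    """
    long_meta = meta[meta["timepoint"].isin(TIMEPOINTS)]
    long_meta = long_meta[long_meta["sample_id"].isin(expr.columns)]
    if long_meta.empty:
        raise ValueError("no longitudinal samples (timepoint set) found in the matrix")
    rows = []
    for pid, grp in long_meta.groupby("patient_id", sort=True):
        tp_map = dict(zip(grp["timepoint"], grp["sample_id"]))
        missing = [tp for tp in TIMEPOINTS if tp not in tp_map]
        if missing or len(grp) != 3:
            raise ValueError(
                f"patient {pid!r} lacks a complete three-timepoint series (missing {missing})"
            )
        sub = expr[[tp_map[tp] for tp in TIMEPOINTS]]
        for fid, (v_pre, v_post, v_rec) in zip(sub.index, sub.to_numpy(dtype=float)):
            rows.append((pid, fid, v_pre, v_post, v_rec))
    return pd.DataFrame(rows, columns=["patient_id", "feature_id", "v_pre", "v_post", "v_rec"])


def evaluate_patient(
    series: pd.DataFrame,
    directions: dict[str, str],
    min_delta: float = 0.0,
) -> pd.DataFrame:
    """Trend calls for every (patient, feature) trajectory.

    ``directions`` maps each feature to its cancer direction (up/down) from
    the screening cascade; every feature in ``series`` must be covered.
    Output order is deterministic: patient, then feature input order.
    """
    uncovered = [f for f in series["feature_id"].unique() if f not in directions]
    if uncovered:
        raise ValueError(f"features without a direction label: {uncovered}")
    rows = []
    for rec in series.itertuples(index=False):
        pattern = call_trend(rec.v_pre, rec.v_post, rec.v_rec, min_delta=min_delta)
        direction = directions[rec.feature_id]
        concordant = pattern == _EXPECTED_PATTERN.get(direction)
        rows.append((rec.patient_id, rec.feature_id, pattern, concordant))
    return pd.DataFrame(rows, columns=["patient_id", "feature_id", "pattern", "concordant"])


def cross_patient_concordance(calls: pd.DataFrame) -> pd.DataFrame:
    """Markers concordant in *every* patient with the same pattern throughout.

    Returns a (feature_id, pattern) table; an empty intersection is a valid
    result, not an error.
    """
    n_patients = calls["patient_id"].nunique()
    if n_patients < 2:
        raise ValueError(
            "cross-patient concordance needs >= 2 patients; "
            "use evaluate_patient for single-patient calls"
        )
    rows = []
    for fid, grp in calls.groupby("feature_id", sort=False):
        if (
            len(grp) == n_patients
            and grp["concordant"].all()
            and grp["pattern"].nunique() == 1
        ):
            rows.append((fid, grp["pattern"].iloc[0]))
    return pd.DataFrame(rows, columns=["feature_id", "pattern"])
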