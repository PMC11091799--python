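"""Aggregation of per-segment acoustic features into participant vectors.

Per-segment values are pooled to one value per recording (mean over the
recording's segments), then the four recordings of a participant are
collapsed to a location and a dispersion statistic per (feature, segment
length).  Whether location/dispersion means mean/SD or median/IQR is decided
per (feature, segment length) over the pooled cohort recording values by an
Anderson-Darling normality test, and the decision is applied uniformly — and
frozen, so held-out participants reuse the decision made on training data.

The resulting participant vector has 23 features x 3 segment lengths x 2
statistics = 138 named entries ``F{code}_L{length}_{loc|disp}``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_CODES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 24))
SEGMENT_LENGTHS: tuple[int, ...] = (5, 10, 15)
N_TASKS = 4

#: MMSE group bands: 1 healthy, 2 mild, 3 moderate-to-severe impairment
GROUP_BANDS = {1: (27, 30), 2: (20, 26), 3: (11, 19)}


def feature_names() -> list[str]:
    """The 138 participant-vector names, in canonical order."""
    return [f"{code}_L{L}_{stat}"
            for code in FEATURE_CODES
            for L in SEGMENT_LENGTHS
            for stat in ("loc", "disp")]


def recording_names() -> list[str]:
    """The 69 per-recording names ``F{code}_L{length}``."""
    return [f"{code}_L{L}" for code in FEATURE_CODES for L in SEGMENT_LENGTHS]


def mmse_to_group(mmse: int) -> int | None:
    """Map an MMSE score to its group, or None outside the 11-30 study range."""
    for g, (lo, hi) in GROUP_BANDS.items():
        if lo <= mmse <= hi:
            return g
    return None


def recording_value(segment_values: Iterable[float]) -> float:
    """Pool one feature's per-segment values into a recording value (mean,
    missing segments excluded).  All-missing -> NaN."""
    vals = np.asarray(list(segment_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def choose_statistic(cohort_values: Sequence[float], alpha: float = 0.05) -> str:
    """Pick ``"mean_sd"`` or ``"median_iqr"`` for one (feature, length) from
    the pooled cohort recording values via the Anderson-Darling normality
    test at *alpha*.  Degenerate or short samples default to the robust pair.
    """
    vals = np.asarray(cohort_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 8:
        warnings.warn("fewer than 8 values; defaulting to median_iqr",
                      stacklevel=2)
        return "median_iqr"
    if np.ptp(vals) == 0.0:
        return "median_iqr"
    res = stats.anderson(vals, dist="norm", method="interpolate")
    return "median_iqr" if res.pvalue < alpha else "mean_sd"


def _loc_disp(vals: np.ndarray, decision: str) -> tuple[float, float]:
    if decision == "mean_sd":
        return float(vals.mean()), float(vals.std(ddof=1))
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])  # type-7 quantiles
    return float(q50), float(q75 - q25)


def aggregate_participant(recording_values: Mapping[str, Sequence[float]],
                          decisions: Mapping[str, str]) -> dict[str, float]:
    """Collapse one participant's per-recording values into the 138-entry
    vector.  *recording_values* maps ``F{code}_L{length}`` to the (up to 4)
    recording values; *decisions* maps the same keys to the cohort-level
    statistic choice.  Fewer than 2 non-missing recordings leave both
    entries missing."""
    out: dict[str, float] = {}
    for key in recording_names():
        vals = np.asarray(list(recording_values.get(key, ())), dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            out[f"{key}_loc"] = float("nan")
            out[f"{key}_disp"] = float("nan")
            continue
        loc, disp = _loc_disp(vals, decisions.get(key, "median_iqr"))
        out[f"{key}_loc"] = loc
        out[f"{key}_disp"] = disp
    return out


def cohort_decisions(recording_table: pd.DataFrame,
                     alpha: float = 0.05) -> dict[str, str]:
    """Anderson-Darling statistic choice per recording-level column, pooled
    over all recordings in *recording_table* (rows = participant x task)."""
    return {key: choose_statistic(recording_table[key].to_numpy(), alpha=alpha)
            for key in recording_names() if key in recording_table.columns}


def aggregate_cohort(recording_table: pd.DataFrame,
                     decisions: Mapping[str, str] | None = None,
                     alpha: float = 0.05
                     ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Aggregate a recording-level table (columns ``participant_id`` plus the
    69 ``F{code}_L{length}`` values, one row per recording) into one row per
    participant.  When *decisions* is None they are computed from this table
    (training data); pass the frozen training decisions to aggregate held-out
    participants without leakage."""
    if decisions is None:
        decisions = cohort_decisions(recording_table, alpha=alpha)
    rows = []
    for pid, grp in recording_table.groupby("participant_id", sort=True):
        rec_vals = {key: grp[key].to_list()
                    for key in recording_names() if key in grp.columns}
        row: dict[str, object] = {"participant_id": pid}
        row.update(aggregate_participant(rec_vals, decisions))
        rows.append(row)
    return pd.DataFrame(rows), dict(decisions)


def attach_groups(cohort: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join participant metadata and derive the MMSE group; participants
    outside the 11-30 MMSE study range are dropped with a warning."""
    merged = cohort.merge(metadata, on="participant_id", how="left",
                          validate="one_to_one")
    merged["group"] = merged["mmse"].map(lambda m: mmse_to_group(int(m)))
    bad = merged["group"].isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} participants with MMSE "
                      "outside the 11-30 study range", stacklevel=2)
        merged = merged[~bad]
    merged["group"] = merged["group"].astype(int)
    return merged.reset_index(drop=True)
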