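"""Cohort tables: participants x measurement grid, outcomes and baseline data.

The on-disk format is a flat CSV with one row per participant:
``participant_id``, ``outcome`` (``fitting`` / ``non_fitting``), the baseline
columns, and one column per measurement named
``<parameter>__<manoeuvre>__<pessary>``.  Empty cells denote missing
measurements; sentinel numbers are never written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VariableKey, variable_grid, ANGLE_PARAMETERS

logger = logging.getLogger(__name__)

FITTING = "fitting"
NON_FITTING = "non_fitting"
OUTCOMES = (FITTING, NON_FITTING)

BASELINE_COLUMNS = (
    "age_years",
    "bmi_kg_m2",
    "parity",
    "family_history_pop",
    "hysterectomy",
    "popq_stage",
    "tvl_exam_cm",
    "postmenopausal",
    "avulsion",
)

AVULSION_LEVELS = ("none", "minor", "major")

_META_COLUMNS = ("participant_id", "outcome") + BASELINE_COLUMNS


@dataclass
class CohortTable:
    """Participants x variables matrix with outcomes and baseline characteristics.

    Parameters
    ----------
    participant_ids
        Unique participant identifiers, in row order.
    outcomes
        Per-participant outcome label, ``fitting`` or ``non_fitting``.
    measurements
        DataFrame of shape (n_participants, n_variables); columns are
        canonical ``VariableKey.column`` names, ``NaN`` marks a missing
        measurement.  Lengths in cm, areas in cm^2, angles in degrees.
    baseline
        DataFrame with the baseline-characteristic columns (may be empty).
    """

    participant_ids: list[str]
    outcomes: list[str]
    measurements: pd.DataFrame
    baseline: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if len(set(self.participant_ids)) != n:
            raise ValueError("participant_id values must be unique")
        if len(self.outcomes) != n or len(self.measurements) != n:
            raise ValueError("row counts of ids, outcomes and measurements disagree")
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(set(bad))}")
        valid = {k.column for k in variable_grid()}
        unknown = [c for c in self.measurements.columns if c not in valid]
        if unknown:
            raise ValueError(f"measurement columns outside the 78-variable grid: {unknown}")

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    @property
    def variable_keys(self) -> list[VariableKey]:
        return [VariableKey.from_column(c) for c in self.measurements.columns]

    def n_per_outcome(self) -> dict[str, int]:
        return {o: self.outcomes.count(o) for o in OUTCOMES}

    def check_ranges(self) -> list[str]:
        """Warn (do not fail) on physically implausible values.

        Lengths/areas should be non-negative and angles inside (0, 360)
        degrees; small-cohort noise or data-entry slips can violate this, so
        the check reports rather than raises.
        """
        problems: list[str] = []
        for col in self.measurements.columns:
            key = VariableKey.from_column(col)
            vals = self.measurements[col].to_numpy(dtype=float)
            obs = vals[~np.isnan(vals)]
            if key.parameter in ANGLE_PARAMETERS:
                if ((obs <= 0) | (obs >= 360)).any():
                    problems.append(f"{col}: angle outside (0, 360) degrees")
            elif (obs < 0).any():
                problems.append(f"{col}: negative length/area")
        for msg in problems:
            logger.warning("range check: %s", msg)
        return problems

    def subset_rows(self, idx: np.ndarray | list[int]) -> "CohortTable":
        idx = np.asarray(idx, dtype=int)
        return CohortTable(
            [self.participant_ids[i] for i in idx],
            [self.outcomes[i] for i in idx],
            self.measurements.iloc[idx].reset_index(drop=True),
            self.baseline.iloc[idx].reset_index(drop=True)
            if len(self.baseline)
            else self.baseline,
        )


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to the flat CSV format (empty cells for missing)."""
    frame = pd.DataFrame({"participant_id": cohort.participant_ids, "outcome": cohort.outcomes})
    if len(cohort.baseline):
        frame = pd.concat([frame, cohort.baseline.reset_index(drop=True)], axis=1)
    frame = pd.concat([frame, cohort.measurements.reset_index(drop=True)], axis=1)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV.

    In strict mode an unknown column or an invalid grid key is fatal; in
    lenient mode such columns are logged and dropped.  Empty cells become
    missing measurements (NaN), never zero.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in frame.columns or "outcome" not in frame.columns:
        raise ValueError("cohort CSV must contain participant_id and outcome columns")
    if frame["participant_id"].duplicated().any():
        dupes = frame["participant_id"][frame["participant_id"].duplicated()].tolist()
        raise ValueError(f"duplicate participant_id values: {dupes}")

    bad_outcomes = set(frame["outcome"]) - set(OUTCOMES)
    if bad_outcomes:
        raise ValueError(f"outcome labels must be in {OUTCOMES}, got {sorted(bad_outcomes)}")

    meas_cols: list[str] = []
    for col in frame.columns:
        if col in _META_COLUMNS:
            continue
        try:
            VariableKey.from_column(col)
        except ValueError as exc:
            if strict:
                raise ValueError(f"invalid measurement column {col!r}: {exc}") from exc
            logger.warning("dropping unrecognised column %r (%s)", col, exc)
            continue
        meas_cols.append(col)

    baseline_cols = [c for c in BASELINE_COLUMNS if c in frame.columns]
    return CohortTable(
        participant_ids=frame["participant_id"].tolist(),
        outcomes=frame["outcome"].tolist(),
        measurements=frame[meas_cols].astype(float),
        baseline=frame[baseline_cols].copy(),
    )
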