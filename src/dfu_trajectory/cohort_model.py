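"""Canonical data model for longitudinal wound-appointment tables.

A cohort is one row per wound-appointment. Mandatory columns are the
identifiers, the two dates and the healing phase; every clinical field may be
missing (empty cell on disk, ``NaN`` in memory). Healing phases are the three
ordinal stages of wound repair: inflammatory (I) < proliferative (P) <
remodeling (R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("I", "P", "R")
#: ordinal encoding used throughout: I=1 < P=2 < R=3
PHASE_ORDINAL = {"I": 1, "P": 2, "R": 3}

CHRONICITY_BINS = ("acute", "subacute", "chronic", "very_chronic")

MANDATORY_COLUMNS = (
    "patient_id",
    "wound_id",
    "appointment_date",
    "wound_onset_date",
    "healing_phase",
)

#: full appointment schema; every non-mandatory field is optional
CLINICAL_COLUMNS = (
    "exudate_amount",        # ordinal 0-3
    "exudate_appearance",    # categorical code
    "temp_wound_center",     # deg C
    "temp_peri_ulcer",       # deg C
    "temp_intact_skin",      # deg C
    "wound_severity",        # ordinal 0-3
    "odor", "erythema", "pallor", "maceration", "edema", "tunneling",
    "neuropathy", "charcot", "claw_toe", "hammer_toe", "bunion",
    "age", "sex", "bmi", "weight", "diabetes_type",
    "wound_location", "offloading_type", "dressing_type",
)

BOOLEAN_COLUMNS = (
    "odor", "erythema", "pallor", "maceration", "edema", "tunneling",
    "neuropathy", "charcot", "claw_toe", "hammer_toe", "bunion",
)

DERIVED_COLUMNS = (
    "derived_appointment_interval_days",
    "derived_days_since_onset",
    "derived_days_in_current_phase",
    "derived_excluded_single_visit",
)


class SchemaError(ValueError):
    """A mandatory column is absent from the input table."""


class ValidationError(ValueError):
    """Row-level contract violation (bad phase code, non-monotone dates...)."""


@dataclass
class CohortTable:
    """Validated appointment table with derived interval fields.

    ``data`` is sorted by (patient_id, wound_id, appointment_date) and carries
    the ``derived_*`` columns:

    - ``derived_appointment_interval_days``: whole days since the previous
      appointment of the same wound (NaN on a wound's first visit, >= 1
      otherwise; same-day duplicates are merged keeping the last record);
    - ``derived_days_since_onset``: appointment date minus wound onset;
    - ``derived_days_in_current_phase``: days from the first appointment of
      the maximal run of consecutive same-phase visits ending here. Time
      before the observation window is not counted;
    - ``derived_excluded_single_visit``: wounds with one appointment carry no
      transition and are flagged excluded from transition analysis.
    """

    data: pd.DataFrame
    issues: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def n_wounds(self) -> int:
        return self.data["wound_id"].nunique()

    def wounds(self):
        """Iterate (wound_id, frame) in appointment order."""
        return self.data.groupby("wound_id", sort=False)


def chronicity_bin(days_since_onset: float) -> str:
    """Bin wound age into acute/subacute/chronic/very_chronic.

    Boundaries follow the clinical convention acute <90 d, subacute
    90-180 d, chronic 180-365 d, very chronic >365 d, realised as the
    disjoint partition [0,90), [90,180), [180,365], (365,inf).
    """
    if days_since_onset < 0 or not np.isfinite(days_since_onset):
        raise ValidationError(f"negative or non-finite wound age: {days_since_onset}")
    if days_since_onset < 90:
        return "acute"
    if days_since_onset < 180:
        return "subacute"
    if days_since_onset <= 365:
        return "chronic"
    return "very_chronic"


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["patient_id", "wound_id", "appointment_date"], kind="stable")
    # merge same-day duplicate visits of one wound, keeping the last record
    df = df.drop_duplicates(subset=["wound_id", "appointment_date"], keep="last")
    df = df.reset_index(drop=True)

    interval = (
        df.groupby("wound_id", sort=False)["appointment_date"].diff().dt.days
    )
    df["derived_appointment_interval_days"] = interval
    df["derived_days_since_onset"] = (
        df["appointment_date"] - df["wound_onset_date"]
    ).dt.days

    # days in current phase: run-length of consecutive same-phase visits
    run_start = np.empty(len(df), dtype="datetime64[ns]")
    for _, idx in df.groupby("wound_id", sort=False).groups.items():
        idx = np.asarray(idx)
        phases = df.loc[idx, "healing_phase"].to_numpy()
        dates = df.loc[idx, "appointment_date"].to_numpy()
        start = dates[0]
        for k in range(len(idx)):
            if k > 0 and phases[k] != phases[k - 1]:
                start = dates[k]
            run_start[idx[k]] = start
    df["derived_days_in_current_phase"] = (
        (df["appointment_date"].to_numpy() - run_start) / np.timedelta64(1, "D")
    ).astype(float)

    n_visits = df.groupby("wound_id", sort=False)["appointment_date"].transform("size")
    df["derived_excluded_single_visit"] = n_visits == 1
    return df


def build_cohort(df: pd.DataFrame, strict: bool = True) -> CohortTable:
    """Validate a raw appointment frame and attach derived fields.

    With ``strict=True`` any contract violation raises; otherwise issues are
    collected on :attr:`CohortTable.issues`.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    df = df.copy()
    for col in ("appointment_date", "wound_onset_date"):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    issues: list[str] = []
    bad_phase = ~df["healing_phase"].isin(PHASES)
    if bad_phase.any():
        vals = sorted(df.loc[bad_phase, "healing_phase"].astype(str).unique())
        issues.append(f"invalid healing_phase value(s): {vals}")

    for wid, grp in df.groupby("wound_id", sort=False):
        # dates must be strictly increasing in the order the file lists them;
        # out-of-order rows indicate an entry error, not a sorting need
        if not grp["appointment_date"].is_monotonic_increasing:
            issues.append(f"non-monotone appointment dates within wound {wid}")
        onset = grp["wound_onset_date"].iloc[0]
        if pd.notna(onset) and onset > grp["appointment_date"].min():
            issues.append(f"wound_onset_date after first appointment for wound {wid}")

    if issues and strict:
        raise ValidationError("; ".join(issues))

    df = _derive(df)
    neg = df["derived_appointment_interval_days"].dropna() < 1
    if neg.any():
        msg = "appointment interval < 1 day after same-day merge"
        if strict:
            raise ValidationError(msg)
        issues.append(msg)
    return CohortTable(data=df, issues=issues)


def read_cohort(path, strict: bool = True) -> CohortTable:
    """Read an appointment CSV (RFC-4180, UTF-8, ISO-8601 dates)."""
    raw = pd.read_csv(path, dtype={"patient_id": str, "wound_id": str})
    return build_cohort(raw, strict=strict)


def write_cohort(cohort: CohortTable, path, derived: bool = True) -> None:
    """Write a cohort back to CSV; derived columns keep their prefix."""
    df = cohort.data.copy()
    if not derived:
        df = df.drop(columns=[c for c in DERIVED_COLUMNS if c in df.columns])
    for col in ("appointment_date", "wound_onset_date"):
        df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
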