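"""Three-category labeling of next-appointment healing-phase transitions.

Each consecutive appointment pair (t, t+1) of a wound is labeled:

- **favorable** — phase progression (I→P, I→R, P→R) or maintained
  remodeling (R→R);
- **acceptable** — phase stability within its chronicity threshold:
  inflammatory persistence I→I up to 21 days, stable proliferation P→P up
  to 42 days (thresholds reflect the expected 2–3 week inflammatory
  resolution window and the 4–6 week proliferative prognostic window);
- **unfavorable** — any phase regression (P→I, R→I, R→P) at any interval,
  prolonged inflammation (I→I beyond 21 days) or prolonged proliferation
  (P→P beyond 42 days).

The duration operand is the cumulative time the wound has occupied its
current phase at the *next* appointment (consecutive same-phase run, see
:mod:`~dfu_trajectory.cohort_model`), not the single inter-visit gap. A
config switch (``duration="since_onset"``) measures it from wound onset
instead.
"""

from __future__ import annotations

import pandas as pd

from .cohort_model import PHASE_ORDINAL, CohortTable

CATEGORIES = ("favorable", "acceptable", "unfavorable")

#: stagnation thresholds in days, per starting phase
INFLAMMATORY_STAGNATION_DAYS = 21
PROLIFERATIVE_STAGNATION_DAYS = 42


def label_transition(phase_t: str, phase_next: str, days_in_phase_at_next: float) -> str:
    """Map one (phase_t, phase_next, duration) triple to its category."""
    for p in (phase_t, phase_next):
        if p not in PHASE_ORDINAL:
            raise ValueError(f"unknown healing phase code: {p!r}")
    if days_in_phase_at_next < 0:
        raise ValueError("days_in_phase_at_next must be >= 0")

    a, b = PHASE_ORDINAL[phase_t], PHASE_ORDINAL[phase_next]
    if b > a:
        return "favorable"
    if b < a:
        return "unfavorable"
    # stable pair
    if phase_t == "R":
        return "favorable"  # maintained remodeling
    limit = (
        INFLAMMATORY_STAGNATION_DAYS if phase_t == "I" else PROLIFERATIVE_STAGNATION_DAYS
    )
    return "acceptable" if days_in_phase_at_next <= limit else "unfavorable"


def label_cohort(cohort: CohortTable, duration: str = "phase_entry") -> pd.DataFrame:
    """Label every consecutive appointment pair of every wound.

    Returns one row per transition with columns ``patient_id, wound_id,
    t_index`` (0-based index of the earlier appointment within its wound),
    phases, dates, the duration operand and ``transition_category``.
    Single-appointment wounds contribute no rows.
    """
    if duration not in ("phase_entry", "since_onset"):
        raise ValueError(f"unknown duration convention: {duration!r}")
    rows = []
    for wid, grp in cohort.wounds():
        if len(grp) < 2:
            continue
        g = grp.reset_index(drop=True)
        for t in range(len(g) - 1):
            nxt = g.loc[t + 1]
            if duration == "phase_entry":
                dur = float(nxt["derived_days_in_current_phase"])
            else:
                dur = float(nxt["derived_days_since_onset"])
            cat = label_transition(g.loc[t, "healing_phase"], nxt["healing_phase"], dur)
            rows.append(
                {
                    "patient_id": g.loc[t, "patient_id"],
                    "wound_id": wid,
                    "t_index": t,
                    "date_t": g.loc[t, "appointment_date"],
                    "date_next": nxt["appointment_date"],
                    "phase_t": g.loc[t, "healing_phase"],
                    "phase_next": nxt["healing_phase"],
                    "days_in_phase_at_next": dur,
                    "transition_category": cat,
                }
            )
    cols = [
        "patient_id", "wound_id", "t_index", "date_t", "date_next",
        "phase_t", "phase_next", "days_in_phase_at_next", "transition_category",
    ]
    return pd.DataFrame(rows, columns=cols)
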