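"""Contiguous-history sequential augmentation of training transitions.

Each transition target can be predicted from every contiguous suffix of its
history: for appointments A1..A5 and target A4 the histories [A1-A3],
[A2-A3] and [A3] each yield a training sample, so a wound with m
appointments contributes m(m-1)/2 samples in total. Non-contiguous
histories (e.g. [A1, A3] -> A5) are never generated — they would violate
the temporal-causality assumptions of the features. Features are recomputed
on the truncated span, treating the span start as the observation start;
wound onset is a wound property and is never truncated. Augmentation is
applied to training folds only; validation samples stay unaugmented.
"""

from __future__ import annotations

import pandas as pd

from .cohort_model import CohortTable


class AugmentationLeakError(RuntimeError):
    """Augmentation was requested for a wound outside the training folds."""


def augment_wound(n_appointments: int, target_index: int) -> list[tuple[int, int]]:
    """Enumerate (span_start, target_index) samples for one target.

    ``target_index`` is the 0-based index of the appointment whose *next*
    transition is predicted; every span start s in {0..target_index} gives
    one contiguous history [s..target_index]. A target with no admissible
    span (negative index) yields an empty list.
    """
    if target_index < 0 or target_index > n_appointments - 2:
        return []
    return [(s, target_index) for s in range(target_index + 1)]


def augment_samples(samples: pd.DataFrame, cohort: CohortTable) -> pd.DataFrame:
    """Expand unaugmented samples into all contiguous-history samples.

    Input rows are (patient_id, wound_id, target_index, span_start=0);
    output carries one row per (wound, target, span_start) with provenance
    columns ``history_start`` / ``history_end`` (0-based appointment indices
    of the span).
    """
    sizes = {wid: len(grp) for wid, grp in cohort.wounds()}
    rows = []
    for r in samples.itertuples(index=False):
        for s, t in augment_wound(sizes[r.wound_id], int(r.target_index)):
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "wound_id": r.wound_id,
                    "target_index": t,
                    "span_start": s,
                    "history_start": s,
                    "history_end": t,
                }
            )
    cols = ["patient_id", "wound_id", "target_index", "span_start", "history_start", "history_end"]
    return pd.DataFrame(rows, columns=cols)


def augment_training_set(
    samples: pd.DataFrame,
    cohort: CohortTable,
    fold_assignment: dict[str, int] | None = None,
    training_folds: set[int] | None = None,
) -> pd.DataFrame:
    """Augment the training partition of a sample table.

    When a fold assignment is given, every sample must belong to a training
    fold; a request covering a validation wound raises
    :class:`AugmentationLeakError` (validation data is never augmented).
    """
    if fold_assignment is not None:
        if training_folds is None:
            raise ValueError("training_folds required with fold_assignment")
        bad = [
            r.patient_id
            for r in samples.itertuples(index=False)
            if fold_assignment.get(r.patient_id) not in training_folds
        ]
        if bad:
            raise AugmentationLeakError(
                f"refusing to augment validation-fold patient(s): {sorted(set(bad))}"
            )
    return augment_samples(samples, cohort)
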