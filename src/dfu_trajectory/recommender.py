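"""Hierarchical case-based treatment recommender (offloading + dressing).

Matches a query presentation against a database of historically successful
appointments — those followed by a favorable phase progression (I→P, P→R,
I→R) or maintaining the advanced remodeling phase (R→R) — using a
tier-weighted similarity

    Similarity(Q, C) = sum_t w_t * sum_{f in F_t} sim_f(q_f, c_f)
                       / sum_t w_t * |F_t|,

with binary local similarity for categorical features and 1 − normalized
absolute difference (min–max range learned from the case base, clipped to
[0,1]) for continuous ones. A missing value on either side contributes
local similarity 0 but still counts in the denominator. Tiers order
clinical decisiveness: critical (treatment-determinative: healing phase,
structural deformity, anatomy), important (severity, demographics,
chronicity), refining (individualization modifiers).

Recommendations take the majority treatment among the top-k most similar
cases (ties broken by higher mean similarity), then apply clinical override
rules — high structural deformity raises the minimum offloading intensity
to moderate protection even for mild acute wounds. Offloading agreement is
scored both exactly (same device) and within-category on the four-point
intensity scale (0 none, 1 low e.g. therapeutic footwear, 2 moderate e.g.
removable walker, 3 high e.g. total contact cast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import CohortTable, chronicity_bin
from .feature_engine import deformity_severity, infection_risk, mobility_risk, moisture_need

#: four-point offloading intensity scale, by device code
OFFLOADING_INTENSITY: dict[str, int] = {
    "none": 0,
    "therapeutic_footwear": 1,
    "modified_footwear": 1,
    "removable_walker": 2,
    "boot": 2,
    "total_contact_cast": 3,
    "assistive_devices": 3,
}

#: deformity score at or above which moderate offloading is enforced
HIGH_DEFORMITY_THRESHOLD = 4.0

_SUCCESS_PAIRS = {("I", "P"), ("P", "R"), ("I", "R"), ("R", "R")}

_CHRONICITY_STAGE = {"acute": 0, "subacute": 1, "chronic": 2, "very_chronic": 3}


@dataclass
class TierConfig:
    """Tier → (weight, {feature: "binary"|"continuous"}) similarity config."""

    tiers: dict[str, tuple[float, dict[str, str]]] = field(
        default_factory=lambda: {
            "critical": (3.0, {
                "healing_phase": "binary",
                "charcot": "binary",
                "deformity_severity": "continuous",
                "wound_location": "binary",
            }),
            "important": (2.0, {
                "wound_severity": "continuous",
                "chronicity_stage": "continuous",
                "age": "continuous",
                "bmi": "continuous",
            }),
            "refining": (1.0, {
                "exudate_amount": "continuous",
                "moisture_need": "continuous",
                "infection_risk": "continuous",
                "mobility_risk": "continuous",
                "neuropathy": "binary",
            }),
        }
    )

    def validate(self) -> None:
        if not self.tiers:
            raise ValueError("tier configuration is empty")
        seen: set[str] = set()
        for name, (w, feats) in self.tiers.items():
            if w <= 0:
                raise ValueError(f"tier {name!r} weight must be positive")
            if not feats:
                raise ValueError(f"tier {name!r} has no features")
            dup = seen & set(feats)
            if dup:
                raise ValueError(f"feature(s) {sorted(dup)} appear in multiple tiers")
            seen |= set(feats)

    def feature_kinds(self) -> dict[str, str]:
        out = {}
        for _, (_, feats) in self.tiers.items():
            out.update(feats)
        return out


def case_features(row) -> dict:
    """Extract the tiered feature view of one appointment row."""
    def get(col):
        v = row[col]
        return np.nan if pd.isna(v) else v

    age = get("age")
    weight = get("weight")
    neuro = get("neuropathy")
    dso = row["derived_days_since_onset"]
    return {
        "healing_phase": get("healing_phase"),
        "charcot": get("charcot"),
        "deformity_severity": deformity_severity(
            bool(row["charcot"]) if pd.notna(row["charcot"]) else False,
            bool(row["claw_toe"]) if pd.notna(row["claw_toe"]) else False,
            bool(row["hammer_toe"]) if pd.notna(row["hammer_toe"]) else False,
            bool(row["bunion"]) if pd.notna(row["bunion"]) else False,
        ),
        "wound_location": get("wound_location"),
        "wound_severity": get("wound_severity"),
        "chronicity_stage": float(_CHRONICITY_STAGE[chronicity_bin(float(dso))])
        if pd.notna(dso)
        else np.nan,
        "age": age,
        "bmi": get("bmi"),
        "exudate_amount": get("exudate_amount"),
        "moisture_need": moisture_need(
            get("exudate_amount") if pd.notna(row["exudate_amount"]) else 0,
            bool(row["maceration"]) if pd.notna(row["maceration"]) else False,
            bool(row["edema"]) if pd.notna(row["edema"]) else False,
            bool(row["tunneling"]) if pd.notna(row["tunneling"]) else False,
        ),
        "infection_risk": infection_risk(
            bool(row["odor"]) if pd.notna(row["odor"]) else False,
            bool(row["erythema"]) if pd.notna(row["erythema"]) else False,
            bool(row["pallor"]) if pd.notna(row["pallor"]) else False,
        ),
        "mobility_risk": mobility_risk(
            age if pd.notna(age) else 0.0,
            weight if pd.notna(weight) else 0.0,
            bool(neuro) if pd.notna(neuro) else False,
        ),
        "neuropathy": neuro,
    }


@dataclass
class CaseDatabase:
    """Successful-case store with learned continuous feature ranges."""

    cases: pd.DataFrame                    # case_id, features..., treatments, outcome
    ranges: dict[str, tuple[float, float]]  # min-max per continuous feature
    tier_config: TierConfig


class EmptyCaseDatabaseError(RuntimeError):
    pass


def build_case_db(
    training_cohort: CohortTable, tier_config: TierConfig | None = None
) -> CaseDatabase:
    """Collect successful appointments from a (training-fold) cohort.

    An appointment qualifies when its realized next-phase pair is a
    favorable progression or maintained remodeling and its treatments are
    recorded.
    """
    tier_config = tier_config or TierConfig()
    tier_config.validate()
    rows = []
    for wid, grp in training_cohort.wounds():
        g = grp.reset_index(drop=True)
        for t in range(len(g) - 1):
            pair = (g.loc[t, "healing_phase"], g.loc[t + 1, "healing_phase"])
            if pair not in _SUCCESS_PAIRS:
                continue
            if pd.isna(g.loc[t, "offloading_type"]) and pd.isna(g.loc[t, "dressing_type"]):
                continue
            feats = case_features(g.loc[t])
            rows.append(
                {
                    "case_id": f"{wid}@{t}",
                    **feats,
                    "offloading_type": g.loc[t, "offloading_type"],
                    "dressing_type": g.loc[t, "dressing_type"],
                    "outcome": "progression" if pair[0] != pair[1] else "maintained_remodeling",
                }
            )
    if not rows:
        raise EmptyCaseDatabaseError(
            "no successful cases found: the training cohort contains no "
            "favorable progressions or maintained remodeling"
        )
    cases = pd.DataFrame(rows)
    kinds = tier_config.feature_kinds()
    ranges = {}
    for feat, kind in kinds.items():
        if kind != "continuous":
            continue
        col = pd.to_numeric(cases[feat], errors="coerce")
        lo, hi = float(col.min()), float(col.max())
        ranges[feat] = (lo, hi)
    return CaseDatabase(cases=cases, ranges=ranges, tier_config=tier_config)


def similarity(
    query: dict,
    case: dict,
    tier_config: TierConfig | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Tier-weighted similarity in [0, 1] between two presentations."""
    tier_config = tier_config or TierConfig()
    tier_config.validate()
    ranges = ranges or {}
    num = 0.0
    den = 0.0
    for _, (w, feats) in tier_config.tiers.items():
        den += w * len(feats)
        for feat, kind in feats.items():
            q, c = query.get(feat), case.get(feat)
            if q is None or c is None or pd.isna(q) or pd.isna(c):
                continue  # missing contributes 0, denominator keeps the slot
            if kind == "binary":
                local = 1.0 if q == c else 0.0
            else:
                lo, hi = ranges.get(feat, (None, None))
                if lo is None or hi is None or hi <= lo:
                    local = 1.0 if float(q) == float(c) else 0.0
                else:
                    local = 1.0 - abs(float(q) - float(c)) / (hi - lo)
                    local = float(np.clip(local, 0.0, 1.0))
            num += w * local
    return num / den


@dataclass
class Recommendation:
    offloading_device: str
    offloading_level: int
    dressing: str
    confidence: float
    matched_case_ids: list[str]


def _vote(values, sims):
    """Majority vote; ties resolved by higher mean similarity."""
    groups: dict = {}
    for v, s in zip(values, sims):
        if pd.isna(v):
            continue
        groups.setdefault(v, []).append(s)
    if not groups:
        return None
    return max(groups.items(), key=lambda kv: (len(kv[1]), float(np.mean(kv[1]))))[0]


def recommend(
    query: dict,
    db: CaseDatabase,
    top_k: int = 5,
    intensity_map: dict[str, int] | None = None,
) -> Recommendation:
    """Recommend offloading and dressing for one query presentation."""
    if db.cases.empty:
        raise EmptyCaseDatabaseError("case database is empty")
    imap = intensity_map or OFFLOADING_INTENSITY
    sims = np.array(
        [similarity(query, dict(row), db.tier_config, db.ranges) for _, row in db.cases.iterrows()]
    )
    k = min(top_k, len(sims))
    top = np.argsort(-sims, kind="stable")[:k]
    top_cases = db.cases.iloc[top]
    top_sims = sims[top]

    device = _vote(top_cases["offloading_type"].tolist(), top_sims) or "none"
    dressing = _vote(top_cases["dressing_type"].tolist(), top_sims) or "saline_gauze"
    level = _device_level(device, imap)

    # clinical override: high structural deformity demands enhanced protection
    deform = query.get("deformity_severity", 0.0)
    if pd.notna(deform) and deform >= HIGH_DEFORMITY_THRESHOLD and level < 2:
        device, level = "removable_walker", 2

    return Recommendation(
        offloading_device=device,
        offloading_level=level,
        dressing=dressing,
        confidence=float(np.mean(top_sims)),
        matched_case_ids=top_cases["case_id"].tolist(),
    )


def _device_level(device: str, imap: dict[str, int]) -> int:
    if device not in imap:
        raise KeyError(f"offloading device code not in intensity mapping: {device!r}")
    return imap[device]


def offloading_match(
    recommended_device: str,
    actual_device: str,
    intensity_map: dict[str, int] | None = None,
) -> dict[str, bool]:
    """Exact (same device) and within-category (|level diff| <= 1) agreement."""
    imap = intensity_map or OFFLOADING_INTENSITY
    lr = _device_level(recommended_device, imap)
    la = _device_level(actual_device, imap)
    return {
        "exact": recommended_device == actual_device,
        "within_category": abs(lr - la) <= 1,
    }


def evaluate_recommender(
    validation_cohort: CohortTable,
    db: CaseDatabase,
    top_k: int = 5,
    intensity_map: dict[str, int] | None = None,
) -> dict:
    """Score recommendations against actual prescriptions, by chronicity.

    Every validation appointment with a recorded actual treatment is a test
    case. Reports overall offloading exact / within-category rates, dressing
    exact-match rate per chronicity bin (missing, not 0, for empty bins) and
    mean confidence.
    """
    imap = intensity_map or OFFLOADING_INTENSITY
    off_exact, off_within, confs = [], [], []
    dress_by_bin: dict[str, list[float]] = {b: [] for b in _CHRONICITY_STAGE}
    n_cases = 0
    for _, grp in validation_cohort.wounds():
        g = grp.reset_index(drop=True)
        for t in range(len(g)):
            row = g.loc[t]
            if pd.isna(row["offloading_type"]) and pd.isna(row["dressing_type"]):
                continue
            q = case_features(row)
            rec = recommend(q, db, top_k=top_k, intensity_map=imap)
            n_cases += 1
            confs.append(rec.confidence)
            if pd.notna(row["offloading_type"]):
                m = offloading_match(rec.offloading_device, row["offloading_type"], imap)
                off_exact.append(float(m["exact"]))
                off_within.append(float(m["within_category"]))
            if pd.notna(row["dressing_type"]) and pd.notna(row["derived_days_since_onset"]):
                cbin = chronicity_bin(float(row["derived_days_since_onset"]))
                dress_by_bin[cbin].append(float(rec.dressing == row["dressing_type"]))

    def rate(xs):
        return float(np.mean(xs)) if xs else np.nan

    return {
        "n_cases": n_cases,
        "offloading_exact_rate": rate(off_exact),
        "offloading_within_category_rate": rate(off_within),
        "dressing_match_rate_by_chronicity": {b: rate(v) for b, v in dress_by_bin.items()},
        "mean_confidence": rate(confs),
    }


def integrate(
    predictions: pd.DataFrame,
    queries: dict,
    db: CaseDatabase,
    only_unfavorable: bool = True,
    top_k: int = 5,
) -> pd.DataFrame:
    """Generate recommendations for flagged predictions.

    ``queries`` maps a prediction key (wound_id, target_index) to its query
    feature dict. By default only predicted-unfavorable transitions trigger
    a recommendation; set ``only_unfavorable=False`` to cover all.
    """
    rows = []
    for r in predictions.itertuples(index=False):
        if only_unfavorable and r.y_pred != "unfavorable":
            continue
        rec = recommend(queries[(r.wound_id, r.target_index)], db, top_k=top_k)
        rows.append(
            {
                "wound_id": r.wound_id,
                "target_index": r.target_index,
                "predicted_category": r.y_pred,
                "offloading_device": rec.offloading_device,
                "offloading_level": rec.offloading_level,
                "dressing": rec.dressing,
                "confidence": rec.confidence,
                "matched_case_ids": ";".join(rec.matched_case_ids),
            }
        )
    cols = [
        "wound_id", "target_index", "predicted_category", "offloading_device",
        "offloading_level", "dressing", "confidence", "matched_case_ids",
    ]
    return pd.DataFrame(rows, columns=cols)
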