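"""Candidate feature pool for next-appointment transition prediction.

Builds, per wound-appointment, a ~110-feature vector spanning six clinical
domains: historical pattern, temporal, temperature, wound assessment,
treatment response and patient phenotype. All historical features are
computed strictly from appointments before the target visit (temporal
causality); the only forward-looking input is the *date* of the next
appointment, which is scheduled and hence known at the current visit.

Feature vectors are computed on an explicit history *span* so the same code
path serves both unaugmented samples (full history) and contiguous-history
augmented samples (truncated spans, see :mod:`~dfu_trajectory.augmentation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_model import (
    BOOLEAN_COLUMNS,
    CLINICAL_COLUMNS,
    PHASE_ORDINAL,
    CohortTable,
    chronicity_bin,
)
from .synthetic_cohort import (
    DRESSING_PRODUCTS,
    EXUDATE_APPEARANCES,
    OFFLOADING_DEVICES,
    WOUND_LOCATIONS,
)
from .transition_labels import label_transition

#: default ordinal complexity of each dressing product (0 = inert carrier,
#: 3 = advanced absorptive/antimicrobial); overridable via config
DRESSING_COMPLEXITY: dict[str, int] = {
    "saline_gauze": 0,
    "betadine": 1,
    "inadine": 1,
    "polysporin": 1,
    "hydrogel": 1,
    "hydrocolloid": 2,
    "foam": 2,
    "mepilex": 2,
    "honey": 2,
    "aquacel": 3,
    "silver_alginate": 3,
    "iodosorb": 3,
}


# ---------------------------------------------------------------------------
# elemental operations


def exponential_recency_weights(n: int, half_life: float = 1.0) -> np.ndarray:
    """Recency weights for the last ``n`` transitions, most recent last.

    Exponential decay with the given half-life (in transitions), normalized
    to sum to 1.
    """
    if n <= 0:
        return np.array([])
    k = np.arange(n - 1, -1, -1, dtype=float)  # age of each transition
    w = 0.5 ** (k / half_life)
    return w / w.sum()


def healing_momentum(phase_deltas, weights=None, n: int | None = None) -> float:
    """Recency-weighted mean of recent signed phase changes.

    Momentum = (1/n) * sum_i w_i * dPhase_i over the last ``n`` transitions,
    where w_i are positive recency weights emphasizing recent transitions
    (default: exponential decay with half-life one transition, normalized to
    sum 1). Empty history is defined as momentum 0 (callers carry a
    separate no-history flag).
    """
    deltas = np.asarray(list(phase_deltas), dtype=float)
    if deltas.size == 0:
        return 0.0
    if n is None:
        n = deltas.size
    n = min(n, deltas.size)
    deltas = deltas[-n:]
    if weights is None:
        w = exponential_recency_weights(n)
    else:
        w = np.asarray(list(weights), dtype=float)[-n:]
        if (w <= 0).any():
            raise ValueError("recency weights must be positive")
    return float(np.sum(w * deltas) / n)


def historical_aggregates(series) -> dict[str, float]:
    """Mean / population sd / min / max of strictly-past values."""
    x = np.asarray([v for v in series if v is not None and not _isnan(v)], dtype=float)
    if x.size == 0:
        return {"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=0)),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def deformity_severity(charcot, claw_toe, hammer_toe, bunion) -> float:
    """Clinically weighted structural-deformity score.

    Charcot arthropathy carries 5 points, claw and hammer toes 2 each,
    bunion 1, reflecting relative impact on offloading requirements.
    """
    return 5.0 * bool(charcot) + 2.0 * bool(claw_toe) + 2.0 * bool(hammer_toe) + 1.0 * bool(bunion)


def mobility_risk(age, weight, neuropathy) -> float:
    """Count of mobility risk indicators.

    Indicators: advanced age (>70 y), elevated weight (>90 kg), sensory
    neuropathy, extreme age (>80 y). Both age indicators can fire at once.
    """
    return float((age > 70) + (weight > 90) + bool(neuropathy) + (age > 80))


def moisture_need(exudate_amount, maceration, edema, tunneling) -> float:
    """Weighted moisture-management score; maceration and tunneling double."""
    return float(exudate_amount) + 2.0 * bool(maceration) + 1.0 * bool(edema) + 2.0 * bool(tunneling)


def infection_risk(odor, erythema, pallor) -> float:
    """Weighted infection warning score; odor carries doubled weight."""
    return 2.0 * bool(odor) + 1.0 * bool(erythema) + 1.0 * bool(pallor)


def treatment_intensity(offloading_active, dressing_complexity) -> float:
    """Active offloading modality count plus ordinal dressing complexity."""
    return float(len(offloading_active)) + float(dressing_complexity)


def treatment_consistency(history) -> float:
    """Fraction of consecutive past treatment pairs left unchanged.

    Histories with fewer than two entries carry no pairs and return NaN.
    """
    codes = [c for c in history]
    if len(codes) < 2:
        return np.nan
    same = sum(1 for a, b in zip(codes[:-1], codes[1:]) if a == b)
    return same / (len(codes) - 1)


def temporal_normalize(delta: float, interval_days: float) -> float:
    """Per-day rate of change across an inter-appointment interval."""
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    return delta / interval_days


def _isnan(v) -> bool:
    try:
        return math.isnan(v)
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# patient phenotyping (fast vs slow healers)


@dataclass
class PhenotypeModel:
    """Frozen k-means phenotyping model fit on training patients only."""

    centroids: np.ndarray          # in standardized metric space
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    fast_cluster: int
    training_metrics: pd.DataFrame

    def predict_cluster(self, Z: np.ndarray) -> np.ndarray:
        d = ((Z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


METRIC_NAMES = ("avg_phase", "healing_velocity", "phase_stability", "treatment_responsiveness")


def patient_trajectory_metrics(cohort: CohortTable) -> pd.DataFrame:
    """Per-patient trajectory metrics for phenotype clustering.

    avg_phase: mean ordinal phase across appointments; healing_velocity:
    net phase change per day pooled over the patient's multi-visit wounds;
    phase_stability: population sd of ordinal phases; treatment
    responsiveness: correlation between a treatment change at one visit and
    a phase improvement at the following visit (0 when undefined).
    """
    rows = []
    for pid, pgrp in cohort.data.groupby("patient_id", sort=False):
        phases = pgrp["healing_phase"].map(PHASE_ORDINAL).to_numpy(dtype=float)
        delta_sum, day_sum = 0.0, 0.0
        changes, improvements = [], []
        for _, wgrp in pgrp.groupby("wound_id", sort=False):
            ph = wgrp["healing_phase"].map(PHASE_ORDINAL).to_numpy(dtype=float)
            dates = wgrp["appointment_date"].to_numpy()
            if len(wgrp) >= 2:
                delta_sum += ph[-1] - ph[0]
                day_sum += float((dates[-1] - dates[0]) / np.timedelta64(1, "D"))
            dress = wgrp["dressing_type"].to_numpy()
            off = wgrp["offloading_type"].to_numpy()
            for t in range(1, len(wgrp) - 1):
                changed = (dress[t] != dress[t - 1]) or (off[t] != off[t - 1])
                changes.append(float(changed))
                improvements.append(float(ph[t + 1] > ph[t]))
        velocity = delta_sum / day_sum if day_sum > 0 else np.nan
        if len(changes) >= 2 and np.std(changes) > 0 and np.std(improvements) > 0:
            responsiveness = float(np.corrcoef(changes, improvements)[0, 1])
        else:
            responsiveness = 0.0
        rows.append(
            {
                "patient_id": pid,
                "avg_phase": float(phases.mean()),
                "healing_velocity": velocity,
                "phase_stability": float(phases.std(ddof=0)),
                "treatment_responsiveness": responsiveness,
            }
        )
    return pd.DataFrame(rows)


def fit_phenotypes(training_cohort: CohortTable, k: int = 2, seed: int = 0) -> PhenotypeModel:
    """K-means (k=2) healer phenotyping on standardized trajectory metrics.

    The cluster with the higher mean (raw-scale) healing velocity is labeled
    *fast* regardless of k-means index ordering. Fit on training patients
    only; apply with :func:`apply_phenotypes` using the frozen centroids and
    training standardization parameters.
    """
    from sklearn.cluster import KMeans

    metrics = patient_trajectory_metrics(training_cohort)
    usable = metrics.dropna(subset=["healing_velocity"])
    if len(usable) < k:
        raise ValueError("need at least k training patients with >=2 appointments")
    M = usable[list(METRIC_NAMES)].to_numpy(dtype=float)
    std = M.std(axis=0, ddof=0)
    if np.all(std == 0):
        raise ValueError("degenerate clustering: all trajectory metrics identical")
    mean = M.mean(axis=0)
    std_safe = np.where(std == 0, 1.0, std)
    Z = (M - mean) / std_safe

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    vel = usable["healing_velocity"].to_numpy()
    cluster_vel = [vel[km.labels_ == c].mean() if (km.labels_ == c).any() else -np.inf for c in range(k)]
    model = PhenotypeModel(
        centroids=km.cluster_centers_,
        scaler_mean=mean,
        scaler_std=std_safe,
        fast_cluster=int(np.argmax(cluster_vel)),
        training_metrics=metrics,
    )
    return model


def apply_phenotypes(model: PhenotypeModel, cohort: CohortTable) -> pd.DataFrame:
    """Assign fast/slow phenotype to every patient of a cohort.

    Patients without computable metrics (e.g. single-visit only) are
    mean-imputed in metric space before nearest-centroid assignment.
    """
    metrics = patient_trajectory_metrics(cohort)
    M = metrics[list(METRIC_NAMES)].to_numpy(dtype=float)
    col_mean = model.scaler_mean
    for j in range(M.shape[1]):
        M[np.isnan(M[:, j]), j] = col_mean[j]
    Z = (M - model.scaler_mean) / model.scaler_std
    clusters = model.predict_cluster(Z)
    return pd.DataFrame(
        {
            "patient_id": metrics["patient_id"],
            "phenotype": np.where(clusters == model.fast_cluster, "fast", "slow"),
        }
    )


# ---------------------------------------------------------------------------
# feature matrix assembly

_CATEGORICAL_LEVELS = {
    "wound_location": WOUND_LOCATIONS,
    "exudate_appearance": EXUDATE_APPEARANCES,
    "offloading_type": OFFLOADING_DEVICES,
    "dressing_type": DRESSING_PRODUCTS,
}

_AGGREGATE_FIELDS = (
    "exudate_amount",
    "wound_severity",
    "temp_wound_center",
    "temp_peri_ulcer",
    "temp_intact_skin",
)

_CHRONICITY_STAGE = {"acute": 0, "subacute": 1, "chronic": 2, "very_chronic": 3}


def _b(v) -> float:
    """Boolean-ish cell to 0/1 float, preserving missing."""
    if v is None or _isnan(v):
        return np.nan
    return 1.0 if bool(v) else 0.0


def _sample_features(g: pd.DataFrame, t: int, s: int, phenotype: str | None,
                     dressing_complexity: dict[str, int]) -> dict[str, float]:
    cur = g.iloc[t]
    hist = g.iloc[s:t]
    span = g.iloc[s : t + 1]
    nxt_date = g.iloc[t + 1]["appointment_date"]
    f: dict[str, float] = {}

    # --- current-visit raw fields
    for col in ("exudate_amount", "wound_severity", "temp_wound_center",
                "temp_peri_ulcer", "temp_intact_skin", "age", "bmi", "weight"):
        f[col] = float(cur[col]) if not pd.isna(cur[col]) else np.nan
    for col in BOOLEAN_COLUMNS:
        f[col] = _b(cur[col])
    f["sex_male"] = np.nan if pd.isna(cur["sex"]) else float(cur["sex"] == "M")
    f["diabetes_type_2"] = (
        np.nan if pd.isna(cur["diabetes_type"]) else float(int(cur["diabetes_type"]) == 2)
    )
    for col, levels in _CATEGORICAL_LEVELS.items():
        v = cur[col]
        for lev in levels:
            f[f"{col}__{lev}"] = np.nan if pd.isna(v) else float(v == lev)

    # --- temperature normalization (site minus same-visit intact skin)
    f["norm_temp_wound_center"] = f["temp_wound_center"] - f["temp_intact_skin"]
    f["norm_temp_peri_ulcer"] = f["temp_peri_ulcer"] - f["temp_intact_skin"]

    # --- composite scores (missing inputs treated as absent/zero)
    def nz(x):
        return 0.0 if (x is None or _isnan(x)) else x

    f["deformity_severity"] = deformity_severity(
        nz(f["charcot"]), nz(f["claw_toe"]), nz(f["hammer_toe"]), nz(f["bunion"])
    )
    f["mobility_risk"] = mobility_risk(nz(f["age"]), nz(f["weight"]), nz(f["neuropathy"]))
    f["moisture_need"] = moisture_need(
        nz(f["exudate_amount"]), nz(f["maceration"]), nz(f["edema"]), nz(f["tunneling"])
    )
    f["infection_risk"] = infection_risk(nz(f["odor"]), nz(f["erythema"]), nz(f["pallor"]))
    device = cur["offloading_type"]
    active = [] if (pd.isna(device) or device == "none") else [device]
    dress = cur["dressing_type"]
    complexity = 0 if pd.isna(dress) else dressing_complexity.get(dress, 0)
    f["treatment_intensity"] = treatment_intensity(active, complexity)

    # --- temporal features (span = observation window)
    dates = span["appointment_date"].to_numpy()
    gaps = (np.diff(dates) / np.timedelta64(1, "D")).astype(float)
    f["appointments_to_date"] = float(t - s + 1)
    f["appointment_interval"] = gaps[-1] if gaps.size else np.nan
    f["appointment_interval_mean"] = float(gaps.mean()) if gaps.size else np.nan
    f["appointment_interval_variability"] = float(gaps.std(ddof=0)) if gaps.size else np.nan
    f["days_to_next_appointment"] = float((nxt_date - cur["appointment_date"]) / pd.Timedelta(days=1))
    dso = float(cur["derived_days_since_onset"])
    f["days_since_onset"] = dso
    f["chronicity_stage"] = float(_CHRONICITY_STAGE[chronicity_bin(dso)])
    f["treatment_duration_days"] = float(
        (cur["appointment_date"] - span.iloc[0]["appointment_date"]) / pd.Timedelta(days=1)
    )

    phases = span["healing_phase"].map(PHASE_ORDINAL).to_numpy(dtype=float)
    # The phase-duration clock is wound-level state known at the visit (like
    # wound age), so it is never truncated by the history span: the run of
    # consecutive same-phase visits is traced over the full record up to t.
    f["days_in_current_phase"] = float(cur["derived_days_in_current_phase"])
    # total days attributed to the current phase over the record up to t
    full_phases = g["healing_phase"].map(PHASE_ORDINAL).to_numpy(dtype=float)
    full_dates = g["appointment_date"].to_numpy()
    full_gaps = (np.diff(full_dates[: t + 1]) / np.timedelta64(1, "D")).astype(float)
    cum = 0.0
    for i in range(t):
        if full_phases[i] == full_phases[t]:
            cum += full_gaps[i]
    f["cumulative_phase_duration"] = cum

    f["phase_ordinal"] = float(phases[-1])
    for name, code in PHASE_ORDINAL.items():
        f[f"phase_{name}"] = float(phases[-1] == code)

    # --- historical pattern features (strictly before t)
    hist_phases = phases[:-1]
    n_hist = hist_phases.size
    for name, code in PHASE_ORDINAL.items():
        cnt = float((hist_phases == code).sum())
        f[f"hist_count_{name}"] = cnt
        f[f"hist_prop_{name}"] = cnt / n_hist if n_hist else np.nan

    deltas = np.diff(phases)
    f["phase_improvement_count"] = float((deltas > 0).sum())
    f["phase_regression_count"] = float((deltas < 0).sum())
    f["phase_stability_count"] = float((deltas == 0).sum())

    # observed transition quality within the span; stagnation durations come
    # from the true phase clock (derived on the full record), matching the
    # convention used for outcome labels
    fav = acc = unf = 0
    ph_full = g["healing_phase"].tolist()
    for i in range(s, t):
        dur = float(g.iloc[i + 1]["derived_days_in_current_phase"])
        cat = label_transition(ph_full[i], ph_full[i + 1], dur)
        fav += cat == "favorable"
        acc += cat == "acceptable"
        unf += cat == "unfavorable"
    f["hist_favorable_transitions"] = float(fav)
    f["hist_acceptable_transitions"] = float(acc)
    f["hist_unfavorable_transitions"] = float(unf)

    f["healing_momentum"] = healing_momentum(deltas, n=3)
    f["no_history_flag"] = float(n_hist == 0)

    for col in _AGGREGATE_FIELDS:
        agg = historical_aggregates(hist[col].tolist())
        for k, v in agg.items():
            f[f"{col}_hist_{k}"] = v

    ex = [v for v in hist["exudate_amount"].tolist() if not pd.isna(v)]
    f["exudate_amount_consistency"] = treatment_consistency(ex)
    f["treatment_consistency_dressing"] = treatment_consistency(
        [v for v in hist["dressing_type"].tolist() if not pd.isna(v)]
    )
    f["treatment_consistency_offloading"] = treatment_consistency(
        [v for v in hist["offloading_type"].tolist() if not pd.isna(v)]
    )
    f["treatment_history_length"] = float(
        sum(1 for _, r in hist.iterrows() if not (pd.isna(r["dressing_type"]) and pd.isna(r["offloading_type"])))
    )
    if n_hist:
        cells = hist[list(CLINICAL_COLUMNS)]
        f["history_completeness"] = float(1.0 - cells.isna().to_numpy().mean())
    else:
        f["history_completeness"] = np.nan

    # mean signed phase change following span visits on the current dressing
    # (within-span surrogate; uses no information beyond the span)
    if pd.isna(dress):
        f["phase_adjusted_treatment_effect"] = np.nan
    else:
        effects = [
            deltas[i]
            for i in range(len(span) - 1)
            if span.iloc[i]["dressing_type"] == dress
        ]
        f["phase_adjusted_treatment_effect"] = float(np.mean(effects)) if effects else np.nan

    # --- phenotype flags
    f["phenotype_fast"] = np.nan if phenotype is None else float(phenotype == "fast")
    f["phenotype_slow"] = np.nan if phenotype is None else float(phenotype == "slow")
    return f


_CATEGORY_RULES = (
    ("temperature", lambda n: "temp" in n),
    ("historical pattern", lambda n: n.startswith("hist_") or "_hist_" in n
     or n in ("history_completeness", "appointments_to_date", "no_history_flag",
              "exudate_amount_consistency")),
    ("treatment response", lambda n: n.startswith(("treatment_", "offloading_type__", "dressing_type__"))
     or n in ("healing_momentum", "phase_adjusted_treatment_effect",
              "phase_improvement_count", "phase_regression_count", "phase_stability_count")),
    ("temporal", lambda n: "interval" in n or "days" in n or "duration" in n
     or n == "chronicity_stage"),
    ("patient phenotype", lambda n: n.startswith("phenotype_")
     or n in ("age", "sex_male", "bmi", "weight", "diabetes_type_2", "neuropathy",
              "charcot", "claw_toe", "hammer_toe", "bunion",
              "deformity_severity", "mobility_risk")),
)


def feature_category(name: str) -> str:
    """Map a feature name to its clinical domain (six-way taxonomy)."""
    for cat, rule in _CATEGORY_RULES:
        if rule(name):
            return cat
    return "wound assessment"


def default_samples(cohort: CohortTable) -> pd.DataFrame:
    """One unaugmented sample per transition: full history span per target."""
    rows = []
    for wid, grp in cohort.wounds():
        pid = grp["patient_id"].iloc[0]
        for t in range(len(grp) - 1):
            rows.append({"patient_id": pid, "wound_id": wid, "target_index": t, "span_start": 0})
    return pd.DataFrame(rows, columns=["patient_id", "wound_id", "target_index", "span_start"])


def build_feature_matrix(
    cohort: CohortTable,
    phenotypes: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    dressing_complexity: dict[str, int] | None = None,
):
    """Assemble the feature matrix for a set of (wound, target, span) samples.

    ``samples`` defaults to :func:`default_samples` (every transition with
    its full history). Returns ``(X, meta)`` where ``X`` is the numeric
    feature frame (missing values preserved for downstream imputation) and
    ``meta`` carries sample provenance (patient, wound, target index, span
    start). A data dictionary is available via :func:`feature_dictionary`.
    """
    if samples is None:
        samples = default_samples(cohort)
    complexity = dressing_complexity or DRESSING_COMPLEXITY
    pheno_map = (
        {} if phenotypes is None else dict(zip(phenotypes["patient_id"], phenotypes["phenotype"]))
    )

    wound_frames = {wid: grp.reset_index(drop=True) for wid, grp in cohort.wounds()}
    feats, meta_rows = [], []
    for row in samples.itertuples(index=False):
        g = wound_frames[row.wound_id]
        t, s = int(row.target_index), int(row.span_start)
        if not 0 <= s <= t <= len(g) - 2:
            raise ValueError(
                f"invalid sample span (start={s}, target={t}) for wound {row.wound_id}"
            )
        pid = g["patient_id"].iloc[0]
        feats.append(_sample_features(g, t, s, pheno_map.get(pid), complexity))
        meta_rows.append(
            {"patient_id": pid, "wound_id": row.wound_id, "target_index": t, "span_start": s}
        )
    X = pd.DataFrame(feats)
    meta = pd.DataFrame(meta_rows)
    return X, meta


#: formula identifiers for engineered features; definitions without an
#: established standard formula are flagged with a "surrogate:" prefix
_FORMULA_IDS = {
    "deformity_severity": "5*charcot + 2*claw + 2*hammer + 1*bunion",
    "mobility_risk": "count(age>70, weight>90, neuropathy, age>80)",
    "moisture_need": "exudate + 2*maceration + edema + 2*tunneling",
    "infection_risk": "2*odor + erythema + pallor",
    "treatment_intensity": "n_active_offloading + dressing_complexity",
    "healing_momentum": "(1/n) sum_i w_i * dPhase_i, exp recency weights",
    "norm_temp_wound_center": "temp_wound_center - temp_intact_skin",
    "norm_temp_peri_ulcer": "temp_peri_ulcer - temp_intact_skin",
    "history_completeness": "surrogate: frac non-missing cells, past visits",
    "exudate_amount_consistency": "surrogate: frac unchanged consecutive grades",
    "phase_adjusted_treatment_effect": "surrogate: mean dPhase after current dressing, in-span",
    "treatment_consistency_dressing": "frac unchanged consecutive codes",
    "treatment_consistency_offloading": "frac unchanged consecutive codes",
}


def _formula_id(name: str) -> str:
    if name in _FORMULA_IDS:
        return _FORMULA_IDS[name]
    if "__" in name:
        return "one_hot"
    if "_hist_" in name:
        return "historical_aggregate(ddof=0)"
    if name.startswith(("hist_", "phase_")) or name.endswith("_count"):
        return "historical_count"
    return "raw"


def feature_dictionary(feature_names) -> pd.DataFrame:
    """Sidecar data dictionary: feature name, clinical category, formula id."""
    names = list(feature_names)
    return pd.DataFrame(
        {
            "feature": names,
            "category": [feature_category(n) for n in names],
            "formula": [_formula_id(n) for n in names],
        }
    )
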