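"""Training pipeline: grouped CV, kNN imputation, Extra Trees, GP-EI HPO.

Cross-validation is patient-level: every appointment of a patient stays in
one fold, so the model never sees a validation patient during training.
Missing values are filled by k-nearest-neighbor imputation (k=5) on
z-scored features, with scaler and imputer fit on training rows only.
The classifier is an extremely-randomized-trees ensemble (random split
thresholds, best-of-random selection), whose impurity importances drive
top-k feature selection. Hyperparameter search uses Bayesian optimization
with a Gaussian-process surrogate and expected-improvement acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.impute import KNNImputer

from .augmentation import augment_training_set
from .cohort_model import CohortTable
from .feature_engine import apply_phenotypes, build_feature_matrix, default_samples, fit_phenotypes
from .metrics import EvaluationReport, evaluate_run
from .transition_labels import CATEGORIES, label_cohort


@dataclass
class ModelConfig:
    """Classifier and pipeline hyperparameters.

    ``n_estimators=400`` and ``max_depth=60`` are the production operating
    point; ``hpo_iterations`` defaults to a desk-scale budget (the full
    2000-iteration search is available by config).
    """

    n_estimators: int = 400
    max_depth: int = 60
    min_samples_leaf: int = 1
    max_features: float = 1.0
    class_weight: str | None = "balanced"
    feature_top_k: int = 30
    knn_imputation_k: int = 5
    hpo_iterations: int = 50
    hpo_search_space: dict = field(
        default_factory=lambda: {
            "n_estimators": (100, 800, "int"),
            "max_depth": (10, 80, "int"),
            "min_samples_leaf": (1, 8, "int"),
            "max_features": (0.2, 1.0, "float"),
        }
    )
    seed: int = 0


# ---------------------------------------------------------------------------
# patient-level stratified folds


def make_folds(labels: pd.DataFrame, n_folds: int = 3, seed: int = 0) -> dict[str, int]:
    """Assign every patient to one fold, balancing category counts greedily.

    ``labels`` needs columns ``patient_id`` and ``transition_category``.
    Patients are processed in decreasing transition count (seeded shuffle for
    ties) and each goes to the fold that minimizes the squared deviation of
    per-category totals.
    """
    patients = labels["patient_id"].unique()
    if len(patients) < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)

    counts = (
        labels.groupby(["patient_id", "transition_category"]).size().unstack(fill_value=0)
    )
    for c in CATEGORIES:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(CATEGORIES)]

    order = counts.index.to_numpy()[rng.permutation(len(counts))]
    order = order[np.argsort(-counts.loc[order].sum(axis=1).to_numpy(), kind="stable")]

    fold_totals = np.zeros((n_folds, len(CATEGORIES)))
    fold_sizes = np.zeros(n_folds)
    assignment: dict[str, int] = {}
    for pid in order:
        vec = counts.loc[pid].to_numpy(dtype=float)
        best, best_cost = 0, np.inf
        for f in range(n_folds):
            trial = fold_totals.copy()
            trial[f] += vec
            cost = float(((trial - trial.mean(axis=0)) ** 2).sum()) + 1e-6 * fold_sizes[f]
            if cost < best_cost:
                best, best_cost = f, cost
        assignment[pid] = best
        fold_totals[best] += vec
        fold_sizes[best] += 1
    # patients without transitions (single-visit only) still need a fold
    for pid in labels["patient_id"].unique():
        assignment.setdefault(pid, int(rng.integers(n_folds)))
    return assignment


# ---------------------------------------------------------------------------
# imputation


def impute_knn(
    X_train: pd.DataFrame,
    X_apply: pd.DataFrame | None = None,
    k: int = 5,
):
    """kNN imputation on z-scored features, fit on training rows only.

    Columns that are entirely missing in training are dropped (with a
    warning) from both frames. Returns the completed training frame, or a
    ``(train, apply)`` pair when ``X_apply`` is given.
    """
    all_missing = [c for c in X_train.columns if X_train[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing column(s): {all_missing}")
        X_train = X_train.drop(columns=all_missing)
        if X_apply is not None:
            X_apply = X_apply.drop(columns=all_missing)

    mean = X_train.mean()
    std = X_train.std(ddof=0).replace(0.0, 1.0)
    Zt = (X_train - mean) / std
    imputer = KNNImputer(n_neighbors=k)
    out_t = pd.DataFrame(
        imputer.fit_transform(Zt) * std.to_numpy() + mean.to_numpy(),
        columns=X_train.columns,
        index=X_train.index,
    )
    if X_apply is None:
        return out_t
    Za = (X_apply - mean) / std
    out_a = pd.DataFrame(
        imputer.transform(Za) * std.to_numpy() + mean.to_numpy(),
        columns=X_apply.columns,
        index=X_apply.index,
    )
    return out_t, out_a


# ---------------------------------------------------------------------------
# classifier


def fit_classifier(X: pd.DataFrame, y, config: ModelConfig | None = None):
    """Fit the extremely-randomized-trees multiclass model.

    Returns ``(model, importances)`` where importances are the impurity-based
    per-feature scores (summing to 1).
    """
    config = config or ModelConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = ExtraTreesClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.max_features,
        class_weight=config.class_weight,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    importances = pd.Series(model.feature_importances_, index=X.columns).sort_values(
        ascending=False
    )
    return model, importances


def select_top_features(importances: pd.Series, k: int = 30) -> list[str]:
    """The k highest-importance features; ties broken by feature name."""
    if k > len(importances):
        raise ValueError("k exceeds feature pool size")
    order = sorted(importances.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order[:k]]


def predict(model, X: pd.DataFrame):
    """Per-class probabilities (columns ordered as CATEGORIES) + argmax."""
    trained = list(getattr(model, "feature_names_in_", []))
    if trained and list(X.columns) != trained:
        raise ValueError("feature set does not match the trained model")
    raw = model.predict_proba(X)
    cols = {c: raw[:, j] for j, c in enumerate(model.classes_)}
    proba = np.column_stack([cols.get(c, np.zeros(len(X))) for c in CATEGORIES])
    labels = np.asarray(CATEGORIES)[proba.argmax(axis=1)]
    return proba, labels


def save_model(path, model, config: ModelConfig, feature_names) -> None:
    """Serialize a fitted model with its config, feature list and a hash of
    the feature data dictionary (so stale artifacts are detectable)."""
    import hashlib

    import joblib

    from .feature_engine import feature_dictionary

    ddict = feature_dictionary(feature_names)
    digest = hashlib.sha256(ddict.to_csv(index=False).encode()).hexdigest()
    joblib.dump(
        {
            "model": model,
            "config": config,
            "feature_names": list(feature_names),
            "data_dictionary_sha256": digest,
        },
        path,
    )


def load_model(path) -> dict:
    import joblib

    return joblib.load(path)


def attribution_summary(model, X: pd.DataFrame, y, seed: int = 0, n_repeats: int = 5) -> pd.DataFrame:
    """Interpretability hook: per-feature attribution summaries.

    Combines the ensemble's impurity importances with permutation importance
    (balanced-accuracy drop on the supplied data) so rankings can be
    cross-checked between a train-time and a behavior-based attribution.
    """
    from sklearn.inspection import permutation_importance

    perm = permutation_importance(
        model, X, y, scoring="balanced_accuracy", n_repeats=n_repeats, random_state=seed
    )
    return pd.DataFrame(
        {
            "feature": X.columns,
            "impurity_importance": model.feature_importances_,
            "permutation_importance": perm.importances_mean,
            "permutation_sd": perm.importances_std,
        }
    ).sort_values("impurity_importance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search (GP surrogate, expected improvement)


def hpo_search(objective, space: dict, iterations: int, seed: int = 0):
    """Maximize ``objective(params)`` over a box search space.

    ``space`` maps parameter name to ``(low, high, "int"|"float")``. The
    first third of the budget (at most 10 trials) is random exploration;
    remaining trials maximize expected improvement under a Gaussian-process
    surrogate (Matern kernel) fit to the observed trials. Returns
    ``(best_params, trials)``; zero iterations returns ``({}, empty log)``.
    """
    trials_cols = list(space) + ["objective"]
    if iterations <= 0:
        return {}, pd.DataFrame(columns=trials_cols)

    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    rng = np.random.default_rng(seed)
    names = list(space)
    lows = np.array([space[n][0] for n in names], dtype=float)
    highs = np.array([space[n][1] for n in names], dtype=float)
    kinds = [space[n][2] for n in names]
    span = highs - lows

    def decode(u: np.ndarray) -> dict:
        vals = lows + u * span
        out = {}
        for j, n in enumerate(names):
            out[n] = int(round(vals[j])) if kinds[j] == "int" else float(vals[j])
        return out

    U, Y = [], []
    n_init = min(10, max(1, iterations // 3))
    for i in range(iterations):
        if i < n_init:
            u = rng.random(len(names))
        else:
            # search runs in the unit cube, so plausible correlation lengths
            # are a fraction of the box; bounding them keeps the few-sample
            # maximum-likelihood fit from collapsing to a flat surrogate
            kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
                nu=2.5, length_scale=0.3, length_scale_bounds=(0.05, 2.0)
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True, random_state=0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.array(U), np.array(Y))
            cand = rng.random((2048, len(names)))
            mu, sd = gp.predict(cand, return_std=True)
            best_y = max(Y)
            sd = np.maximum(sd, 1e-12)
            xi = 0.01  # exploration margin
            z = (mu - best_y - xi) / sd
            from scipy.stats import norm

            ei = (mu - best_y - xi) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        params = decode(u)
        val = float(objective(params))
        U.append(u)
        Y.append(val)

    trials = pd.DataFrame([{**decode(u), "objective": y} for u, y in zip(U, Y)])
    best = trials.loc[trials["objective"].idxmax()]
    best_params = {n: (int(best[n]) if space[n][2] == "int" else float(best[n])) for n in names}
    return best_params, trials


# ---------------------------------------------------------------------------
# end-to-end cross-validated run


def subset_cohort(cohort: CohortTable, patient_ids) -> CohortTable:
    keep = cohort.data["patient_id"].isin(set(patient_ids))
    return CohortTable(data=cohort.data[keep].reset_index(drop=True))


@dataclass
class CrossValResult:
    report: EvaluationReport
    predictions: pd.DataFrame
    importances: pd.Series          # mean impurity importances over folds
    fold_assignment: dict[str, int]
    selected_features: list[str]


def cross_validate_pipeline(
    cohort: CohortTable,
    config: ModelConfig | None = None,
    n_folds: int = 3,
    augment: bool = True,
    use_phenotypes: bool = True,
    select_features: bool = True,
) -> CrossValResult:
    """Run the full leakage-safe pipeline and evaluate out-of-fold.

    Per fold: phenotypes are fit on training patients only; training
    transitions are expanded by contiguous-history augmentation (validation
    stays unaugmented); imputation is fit on training rows; top-k feature
    selection is nested inside the fold; the Extra Trees model predicts the
    held-out patients.
    """
    config = config or ModelConfig()
    labels = label_cohort(cohort)
    if labels.empty:
        raise ValueError("cohort contains no transitions")
    label_map = {
        (r.wound_id, r.t_index): r.transition_category for r in labels.itertuples(index=False)
    }
    folds = make_folds(labels, n_folds=n_folds, seed=config.seed)

    pred_rows = []
    fold_importances = []
    selected_union: list[str] = []
    for v in range(n_folds):
        train_pids = [p for p, f in folds.items() if f != v]
        valid_pids = [p for p, f in folds.items() if f == v]
        train_cohort = subset_cohort(cohort, train_pids)
        valid_cohort = subset_cohort(cohort, valid_pids)

        phen_train = phen_valid = None
        if use_phenotypes:
            model_ph = fit_phenotypes(train_cohort, seed=config.seed)
            phen_train = apply_phenotypes(model_ph, train_cohort)
            phen_valid = apply_phenotypes(model_ph, valid_cohort)

        train_samples = default_samples(train_cohort)
        if augment:
            train_samples = augment_training_set(
                train_samples, train_cohort, folds, training_folds=set(range(n_folds)) - {v}
            )
        valid_samples = default_samples(valid_cohort)

        Xt, meta_t = build_feature_matrix(train_cohort, phen_train, train_samples)
        Xv, meta_v = build_feature_matrix(valid_cohort, phen_valid, valid_samples)
        yt = np.array(
            [label_map[(r.wound_id, r.target_index)] for r in meta_t.itertuples(index=False)]
        )
        yv = np.array(
            [label_map[(r.wound_id, r.target_index)] for r in meta_v.itertuples(index=False)]
        )

        Xt, Xv = impute_knn(Xt, Xv, k=config.knn_imputation_k)
        _, importances = fit_classifier(Xt, yt, config)
        fold_importances.append(importances)

        if select_features and config.feature_top_k < Xt.shape[1]:
            feats = select_top_features(importances, config.feature_top_k)
            Xt_sel, Xv_sel = Xt[feats], Xv[feats]
        else:
            feats = list(Xt.columns)
            Xt_sel, Xv_sel = Xt, Xv
        selected_union = sorted(set(selected_union) | set(feats))

        model, _ = fit_classifier(Xt_sel, yt, config)
        proba, pred = predict(model, Xv_sel)
        for i in range(len(yv)):
            pred_rows.append(
                {
                    "fold": v,
                    "patient_id": meta_v.iloc[i]["patient_id"],
                    "wound_id": meta_v.iloc[i]["wound_id"],
                    "target_index": meta_v.iloc[i]["target_index"],
                    "y_true": yv[i],
                    "y_pred": pred[i],
                    **{f"proba_{c}": proba[i, j] for j, c in enumerate(CATEGORIES)},
                }
            )

    predictions = pd.DataFrame(pred_rows)
    report = evaluate_run(predictions)
    importances = (
        pd.concat(fold_importances, axis=1).fillna(0.0).mean(axis=1).sort_values(ascending=False)
    )
    return CrossValResult(
        report=report,
        predictions=predictions,
        importances=importances,
        fold_assignment=folds,
        selected_features=selected_union,
    )


def tune_model(
    cohort: CohortTable,
    base_config: ModelConfig | None = None,
    iterations: int | None = None,
    n_folds: int = 3,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Bayesian HPO over the classifier space; objective = CV weighted F1."""
    base = base_config or ModelConfig()
    iters = base.hpo_iterations if iterations is None else iterations
    if iters <= 0:
        return base, pd.DataFrame()

    def objective(params):
        cfg = replace(base, **params)
        res = cross_validate_pipeline(cohort, cfg, n_folds=n_folds)
        return res.report.summary["weighted_f1_mean"]

    best_params, trials = hpo_search(objective, base.hpo_search_space, iters, seed=base.seed)
    return replace(base, **best_params), trials
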