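# Methods

This note documents the models, conventions and design choices behind
`dfu-trajectory`: a pipeline that predicts the healing-phase transition a
diabetic foot ulcer (DFU) will realize at its *next* clinical appointment,
and recommends offloading/dressing interventions for predicted-unfavorable
trajectories.

## Clinical formulation

Wound healing is staged ordinally as inflammatory (I) < proliferative (P) <
remodeling (R). For each consecutive appointment pair (t, t+1) of a wound we
assign one of three outcome categories:

- **favorable** — progression (I→P, I→R, P→R) or maintained remodeling
  (R→R);
- **acceptable** — phase stability inside its chronicity window:
  I→I for at most 21 days in phase, P→P for at most 42 days in phase;
- **unfavorable** — any regression (P→I, R→I, R→P) regardless of interval,
  or stagnation beyond the 21 / 42-day thresholds.

The thresholds encode the expected 2–3 week inflammatory resolution window
and the 4–6 week proliferative prognostic window used in DFU practice. The
duration operand is the cumulative time the wound has occupied its current
phase at appointment t+1, measured from the first observed appointment of
the current same-phase run (time before the observation window is unknown
and not counted). An alternative convention measuring from wound onset is
available as a config switch (`duration="since_onset"`), but the phase-entry
reading is the default because the thresholds describe persistence *in a
phase*, not wound age.

Boundary conventions worth stating exactly: chronicity bins partition wound
age as [0, 90) acute, [90, 180) subacute, [180, 365] chronic, (365, ∞) very
chronic, so the conventional labels "90–180", "180–365", ">365" are
disjoint. Appointment intervals are whole days, at least 1; same-day
duplicate visits for a wound are merged keeping the last record.

## Synthetic cohort generator

The clinical dataset this line of work rests on is restricted; the
generator reproduces its published statistical structure so the pipeline is
testable end to end:

- **Scale**: default 268 patients; wounds per patient 1 + Poisson(0.23)
  (≈1.23 wounds/patient); appointments per wound 1 + NegBin matched to
  mean 2.7, sd 2.2, capped at 17. Single-appointment wounds are generated
  and excluded from transition analysis, as in the source cohort.
- **Visit spacing**: log-normal with median 21 d (fixes μ = ln 21) and mean
  33.4 d (fixes σ ≈ 0.96). The implied sd (~41 d) slightly exceeds the
  published 36 d; only two moments and a median are published, and the
  family choice favors the heavy right tail typical of wound-clinic
  scheduling.
- **Phase dynamics**: a first-order Markov chain per latent healer
  phenotype (fast/slow, default mix 50/50). A stationary chain necessarily
  has zero net phase drift, so positive healing velocity and the published
  visit-to-visit transition mix can only coexist on finite, non-stationary
  trajectories. The default matrices and the initial phase distribution
  (I 0.529, P 0.471, R 0) were therefore calibrated against *finite-horizon*
  expected statistics under the appointments-per-wound distribution, using
  the same simplex search exposed as `calibrate_markov`. Achieved values:
  appointment-level phase prevalence ≈ 31/56/13%, transition mix ≈
  22/65/13% (improvement/stable/regression), and net drift ≈ 0.0095 vs
  0.0028 phase-units/day for fast vs slow healers (published clusters:
  0.012 ± 0.008 vs 0.003 ± 0.005).
- **Covariates** are drawn phase-conditionally (inflamed wounds are warmer
  — site-minus-intact-skin elevation 2.2/1.2/0.4 °C for I/P/R — wetter and
  more symptomatic), demographics match the published cohort (age 62.3 ±
  11.7, 79% male, wound-age mixture 31/16/15/38% across chronicity bins).
- **Treatments** follow noisy protocol-like rules. Offloading intensity
  rises with structural deformity and wound severity. Dressing choice is
  protocol-driven for wounds up to a year old (infection → iodine-based,
  high exudate → absorptive, otherwise inert/simple, with 20–30% deviation)
  and an individualized rotating trial for very chronic (>365 d) wounds —
  emulating the documented clinical reality that treatment-resistant wounds
  receive iterative experimentation rather than standardized protocols.
  This makes recommender agreement decline with chronicity by
  construction, mirroring the behavior of the real system.
- **Missingness** is MCAR at 4.57% across all clinical fields (the
  mechanism of the real data is uncharacterized; MCAR is the neutral
  choice).
- **Planted effects** tilt next-phase odds by standardized covariate values
  (positive tilt multiplies regression odds by exp(tilt) and improvement
  odds by exp(−tilt)). The planted-signal study condition used by the
  acceptance checks is a unit effect of the log gap to the next
  appointment, i.e. one log-sd of extra waiting multiplies regression odds
  by e — a strong, recoverable driver.

What the generator does **not** emulate: joint feature dependence beyond the
published marginals, informative missingness, treatment feedback on phase
dynamics (prescriptions do not alter the chain), or inter-wound correlation
within a patient beyond the shared phenotype. Passing tests therefore
demonstrate that the pipeline recovers structure it is designed to recover —
not clinical performance on real data.

## Feature engineering

Each training sample is the feature vector at appointment t (given a history
span) paired with the label at t+1, ~111 features across six domains
(historical pattern, temporal, temperature, wound assessment, treatment
response, patient phenotype). Conventions:

- Temporal causality: nothing after t is used, with one deliberate
  exception — the *date* of appointment t+1 ("days to next appointment"),
  which is scheduled and known at t and never reveals outcomes.
- Standard deviations are population (ddof 0) throughout.
- Normalized temperatures are site minus same-visit intact skin.
- Healing momentum is (1/n) Σ wᵢ·ΔPhaseᵢ over the last n = 3 transitions
  with exponential recency weights (half-life one transition, normalized to
  sum 1); empty history is momentum 0 plus a no-history flag.
- Composite scores use the clinical weights: deformity 5·Charcot +
  2·claw + 2·hammer + 1·bunion; mobility risk counts age>70, weight>90 kg,
  neuropathy, age>80 (both age indicators may fire); moisture need
  exudate + 2·maceration + edema + 2·tunneling; infection risk 2·odor +
  erythema + pallor; treatment intensity = active offloading modalities +
  ordinal dressing complexity (shipped 0–3 mapping per product,
  configurable).
- Surrogate definitions (feature names in common clinical-ML use that have
  no single established formula; flagged as such in the data dictionary):
  *history completeness* =
  fraction of non-missing clinical cells over past visits; *exudate amount
  consistency* = fraction of consecutive past visits with unchanged exudate
  grade; *phase-adjusted treatment effect* = mean signed phase change
  following within-span visits on the current dressing (span-local, hence
  leakage-free by construction).

Healer phenotyping is k-means (k=2) on four standardized per-patient
trajectory metrics (mean phase, healing velocity, phase stability,
treatment responsiveness), fit on training patients only; the cluster with
higher raw healing velocity is labeled *fast* irrespective of k-means index
order, and application uses frozen centroids and training standardization.

## Augmentation and the phase-clock convention

Training transitions are expanded by contiguous-history augmentation: for a
target appointment, every contiguous suffix of its history yields a sample
(a wound with m appointments contributes m(m−1)/2 samples). Non-contiguous
histories are never formed. Validation data is never augmented, and a
request to augment a validation wound is a hard error.

Features on truncated spans treat the span start as the observation start —
with one considered exception. The phase-duration clock
(`days_in_current_phase`, `cumulative_phase_duration`, and the durations
inside historical transition-quality counts) always uses the true
backward-looking phase run, like wound age. Truncating the clock creates
samples whose visible duration contradicts the stagnation-threshold label
of their own target (the label is a property of the transition, not of the
observation window); in ablation experiments that inconsistency injected
label noise into augmented samples only and reversed the expected benefit
of augmentation. With the consistent clock, augmentation improves
cross-validated weighted F1 on the planted-signal cohorts, matching the
direction expected of the method.

## Model pipeline

- Patient-level 3-fold cross-validation: all appointments of a patient stay
  in one fold; folds are balanced greedily on transition-category counts
  (each patient goes to the fold minimizing squared deviation of category
  totals). Phenotype fitting, imputation, feature selection and training
  are all nested inside the fold.
- Missing values: kNN imputation (k=5) on z-scored features, fit on
  training rows only; all-missing columns are dropped with a warning.
- Classifier: extremely randomized trees, defaults 400 estimators / depth
  60 / balanced class weights (an oversampling switch exists but is off by
  default to protect calibration). Desk-scale runs in the tests and the
  reproduction script use 150 trees — the operating point is insensitive
  well before 400 trees at these sample sizes.
- Feature selection: top-30 impurity importances, ties broken by name,
  nested per fold (a global mode exists but per-fold is the leakage-safe
  default).
- Hyperparameter search: Gaussian-process (Matern ν=2.5, bounded
  length-scale on the unit cube) surrogate with expected-improvement
  acquisition over n_estimators 100–800, max_depth 10–80, min_samples_leaf
  1–8, max_features 0.2–1.0; desk default 50 iterations, the production
  budget (2000) available by config. The objective is cross-validated
  weighted F1.

## Evaluation

Balanced accuracy (mean per-class recall — reported as "accuracy" for this
task), per-class precision/recall/F1 and weighted F1, one-vs-rest
TPR/FPR/TNR/FNR with exact complementarity, per-class and mean one-vs-rest
rank AUC, and expected calibration error with 10 equal-width bins per class
under one-vs-rest decomposition (bin count configurable; the binning scheme
is a declared default, not inherited). Per-fold aggregates are mean ± sd;
reliability-curve points are exported as data rather than figures.

## Treatment recommender

Successful cases are appointments followed by favorable progression (I→P,
P→R, and also I→R, which the label rules class as progression) or
maintained remodeling (R→R), drawn from training folds only. Similarity is
the tier-weighted mean of local similarities (binary for categoricals,
1 − min-max-normalized absolute difference for continuous, learned from the
case base and clipped to [0,1]); a missing value on either side contributes
0 but stays in the denominator (conservative). Default tier weights are
critical 3, important 2, refining 1; tier membership is a shipped,
configurable default (healing phase, Charcot, deformity severity and
anatomy in the critical tier; severity, chronicity and demographics
important; wound-bed modifiers refining). Recommendations take the majority
treatment of the top-5 most similar cases (ties to higher mean similarity);
confidence is the mean similarity of the voting cases — a pragmatic
definition; there is no canonical confidence measure for CBR votes. One
clinical override is applied: deformity score ≥ 4 raises the minimum
offloading intensity to level 2 (moderate protection even for mild acute
wounds). Offloading agreement is scored exactly (same device) and within
category (±1 level on the 0–3 intensity scale: none / therapeutic–modified
footwear / removable walker–boot / total contact cast–assistive devices);
dressing agreement is exact-only, stratified by chronicity bin.

## Problem sizes and numerical choices

The test-suite and reproduction-script study conditions are 300-patient
planted-signal cohorts (~650 transitions, ~1,500 augmented samples), 3
folds, 150-tree forests, 5 seeds for recovery and 10 for the ablation —
sizes chosen so the full experiment battery completes on a single CPU in
minutes while keeping every comparison comfortably away from its decision
boundary. Markov calibration accepts printed rounded mixes (sum within
5·10⁻³ of 1, renormalized), snaps probabilities below 10⁻⁶ to zero, and
prefers minimal off-diagonal mass among exact fits so an all-stable target
returns the identity chain. Degenerate inputs fail loudly: zero patients,
empty case databases, single-class training labels, all-identical
clustering metrics.

## Known limitations

- The generator's conditional independence of covariates given phase
  understates real feature correlation; absolute metric values on synthetic
  cohorts are not forecasts of clinical performance.
- Phenotype recovery on default cohorts is imperfect (~0.67 agreement with
  latent truth) because short trajectories carry little velocity
  information; the well-separated-cluster regime is exercised separately in
  tests.
- The recommender's exact-match rates depend strongly on how concentrated
  the simulated prescribing protocol is; only the chronicity *gradient* is
  structural.
- Interpretability exports are impurity and permutation importances; no
  Shapley-value decomposition is bundled.
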