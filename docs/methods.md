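# Methods

This note documents the models, default parameters, numerical choices and
limitations of `synthpool`. It describes what the code computes; every
number quoted as behavior is produced by the test suite or
`scripts/acceptance.py`, not asserted from elsewhere.

## 1. The study design being emulated

Two countries hold harmonized health-survey microdata (twelve variables:
sex, 7-level age group, BMI < 25 indicator, hypertension, diabetes,
smoking, 3-level marital status, 5-level household size, 4-level education,
3-level household income, immigrant status, country). Country A's table is
replaced by m synthetic replicates, each pooled with country B's real
table, and linear regressions of the modified CANHEART cardiovascular-
health score (0–4, the count of ideal states among non-smoking, BMI < 25,
no diabetes, no hypertension) are fitted on each pooled dataset and
combined. The ground truth is the same regression computed exactly on the
two real tables by federated least squares. Utility is judged by covariate
balance (SMD) and by whether the combined pooled fits reach the same
analytic conclusions as the oracle; privacy by a membership-disclosure
attack on the synthetic replicates.

## 2. Survey simulator (ground truth)

The real surveys are restricted-access, so the simulator generates tables
with the structure the analysis assumes.

* **Demographics** are independent draws from per-variable marginal
  targets. The stock `canada_like` / `austria_like` specs hard-code the
  published marginal percentages of the two surveys (normalized to sum to
  one, since printed values round to one decimal).
* **Risk factors** follow logistic models in ordinal age score (1–7,
  centred at 4), income score (1–3, centred at 2) and education score
  (1–4, centred at 2.5). Default log-odds per unit (`DEFAULT_EFFECT_LOGITS`)
  encode conventional epidemiological gradients, e.g. hypertension +0.75
  per age level, smoking −0.30 per education level; the true dependence
  structure of the source surveys is unobservable, so these are free,
  documented parameters. Intercepts are calibrated per sex by root-finding
  (`brentq`, tolerance 1e-12) so the realized male and female prevalences
  hit the published sex-specific targets exactly in expectation.
* **Missingness** is MCAR per variable at the per-variable nonresponse
  rates implied by the published per-variable Ns (e.g. BMI 6.7% in the
  Canada-like spec; smoking 22.5% in the Austria-like spec). No
  informative-missingness mechanism is claimed by the source material, so
  none is simulated — a limitation for anyone reading the missing-data
  behavior as realistic.
* **BMI** is simulated directly as the binary "< 25" indicator, the only
  form the index and the balance tables use; an optional continuous BMI
  column (truncated normals on either side of 25 kg/m², consistent with
  the indicator) exercises the continuous synthesis path. Underweight is
  counted as ideal because the index is defined on "< 25" as printed.
* Age enters all models as the ordinal score 1–7; education and household
  size as ordinal scores; income is reverse-coded (low = 3 … high = 1) in
  the modelling layer only — single-coefficient table rows imply ordinal
  codings, and this is the minimal one consistent with them.

What passing tests show about real data: the pipeline preserves marginals,
pairwise associations and regression conclusions *for data with this
dependence structure* (logistic main effects, MCAR missingness). Real
surveys have survey weights, cluster/strata design, informative
nonresponse and higher-order interactions, none of which are simulated;
conclusions about the pipeline's behavior on real microdata are
correspondingly weaker.

## 3. Sequential synthesis

Variables are synthesized in schema order by default. Each conditional is
a LightGBM model of the target given all earlier variables.

* **Tuning.** Hyperparameters (boosting rounds 20–300, leaves 4–64,
  learning rate 0.01–0.3, min leaf size 5–100, all log-scaled) are chosen
  by a small Bayesian-optimization loop: five-fold CV scores (log-loss /
  squared error), a Matérn-5/2 Gaussian-process surrogate on the unit
  cube, expected-improvement acquisition over random candidates; default
  budget 25 trials, first 8 random. With `n_trials=0` the search is
  skipped in favour of fixed defaults (60 rounds, 15 leaves, lr 0.1, min
  leaf 40) — the desk-scale pipeline setting, chosen so a full study run
  stays under a minute; the search remains one config change away.
* **Class imbalance and calibration.** Classifiers are trained with
  inverse-frequency class weights, which (together with boosting itself)
  distorts predicted probabilities; each class therefore carries a
  one-vs-rest beta-calibration map fitted on out-of-fold predictions
  (never training-fold ones), renormalized across classes at sampling
  time. Sampling draws from the calibrated class probabilities.
* **Continuous variables** are mapped to normal scores via the empirical
  CDF with the rank/(n+1) convention (average ranks for ties, so scores
  stay finite and the forward map is single-valued), modelled by a
  regressor on that scale, and sampled as point prediction plus a
  bootstrap draw from the out-of-fold residual pool — boosting emits point
  predictions only, so residual bootstrap is how stochasticity is
  injected. The inverse transform interpolates linearly between support
  points and clips to the training min/max.
* **Missing values** are first-class: an explicit extra category level for
  categoricals, a synthesized missing-indicator plus 0-imputed score for
  continuous variables; both are restored to empty cells on output.
* **Determinism.** LightGBM runs single-threaded with
  `deterministic=true`; replicate i draws from a child generator seeded by
  `SeedSequence([seed, i])`, so replicates are independent yet individually
  reproducible, and a saved/reloaded model archive (a single JSON file,
  tree ensembles as model strings) samples bit-identically.
* **Ordering heuristic.** An opt-in greedy order (`order="auto"`) starts
  from the lowest-entropy variable and appends the variable most
  predictable from those placed (3-fold CV of a shallow decision tree); the
  default remains schema order, and the choice is logged.
* The CANHEART score is recomputed from synthesized components rather than
  synthesized as its own column, so the index–component consistency is
  exact by construction.

## 4. Beta calibration

The three-parameter family μ(p) = 1/(1 + 1/(e^c p^a (1−p)^{−b})) is fitted
by exact maximum likelihood: Newton–Raphson on the logistic log-likelihood
with features (ln p, −ln(1−p)), gradient tolerance 1e-12, a 1e-10 ridge for
the nearly collinear feature pair, and step damping near separability.
Exact convergence matters: the intercept score equation then forces the
mean calibrated probability to equal the base rate on the fitting sample,
which is what keeps synthetic marginals unbiased. If the unconstrained fit
gives a < 0 (or b < 0) the offending feature is dropped and the model
refitted; if a slope is still negative the map falls back to the constant
base-rate map. Probabilities are clipped to [1e-6, 1−1e-6] before the log
features. Multiclass targets use one-vs-rest maps with renormalization —
the binary mechanics generalized in the simplest way. Calibration is fitted
once per final model, on out-of-fold predictions.

## 5. Combining rules

For m ≥ 2 replicates with per-replicate estimates qᵢ and variances vᵢ:
q̄_m = mean(qᵢ), v̄_m = mean(vᵢ), b_m = Σ(qᵢ−q̄_m)²/(m−1),
T_p = b_m/m + v̄_m, CI = q̄_m ± 1.96·√T_p, p-value from the normal
reference. These are the *partial-synthesis* rules — only one country's
table is synthetic — not the fully-synthetic variants. Inference is
large-sample normal with the 1.96 multiplier and no small-m degrees-of-
freedom correction. m = 1 is refused explicitly (there is no
between-replicate variance to estimate). The default study uses m = 5 at
desk scale; m = 10 is one config change.

## 6. Membership disclosure

Targets (half members of the synthesis training data, half not, by
default) are matched to the synthetic table by mean per-variable distance
over demographic quasi-identifiers (categorical 0/1 mismatch, missing
matching missing; continuous absolute difference scaled by the synthetic
range, capped at 1). A target within threshold h of its nearest synthetic
record is predicted a member. The reported metric is the relative F1:
attack F1 minus the naive baseline 2t/(1+t) that predicts everyone a
member at member fraction t.

By default the adversary is granted their best case: h is chosen to
maximize the attack F1 over all achievable distance values ("adaptive").
A fixed h (including the strict exact-match h = 0) is configurable. The
adaptive default was chosen because a fixed strict threshold penalizes
recall for members and non-members alike when the synthetic table is
smaller than the quasi-identifier space, pushing relative F1 *negative*
— an artifact of the baseline's recall advantage, not evidence of privacy;
the best-threshold formulation anchors the independence null at 0 (the
adversary can always fall back to predict-everyone) while leaving a
memorizing synthesizer fully exposed (relative F1 = 1 − naive F1). With
multiple replicates the attack runs per replicate and metrics are averaged.
The privacy result is reported, never enforced, unless the CLI's
`--fail-on-privacy` threshold is set.

## 7. Federated least squares

Each node computes X′X, X′y, y′y and n over its complete cases for a given
model; the solver sums them and solves the normal equations. This is
algebraically the pooled fit — coefficients, coefficient variances,
residual variance and R² agree with direct pooled OLS to at least 1e-8
relative (tested on random 2/3/5-way partitions). Complete-case analysis
is per model, matching per-variable N reporting and the absence of any
imputation step for the analysis models. Rank deficiency falls back to the
pseudo-inverse with an explicit aliasing warning. The three model
families are: eight univariable regressions, the multivariable main-effects
model, and the interaction model (every predictor × country product plus
main effects, country reference = the synthesized country).

## 8. Utility metrics

* **SMD.** Continuous/ordinal: |m_a − m_b|/√((s_a²+s_b²)/2); binary: the
  same with p(1−p) variances; multi-level categorical: the Mahalanobis-type
  SMD over level-proportion vectors (one level dropped, average multinomial
  covariance), chosen to give one number per variable as in the published
  balance-table layout; a per-level maximum is available as an option.
  SMDs are computed per replicate against the ground-truth pooled table and
  averaged, overall and within sex strata (both produced, since the
  published layout implies but does not state the stratified version);
  mean SMD > 0.1 is flagged. Zero pooled variance with unequal means
  returns +inf with a warning.
* **Concordance.** Per coefficient: sign agreement (same sign, or both CIs
  containing 0), significance agreement at p < 0.05 uncorrected, and CI
  overlap. "Same conclusions" is operationalized as these three flags;
  the original comparison is narrative.

## 9. Pipeline defaults and problem sizes

The default study simulates country A at n = 20,000 and country B at
n = 5,000 with m = 5 replicates and no hyperparameter search — sizes chosen
so one full run completes in well under a minute on a single CPU and the
ten-seed concordance panel in a few minutes, while remaining large enough
that 3·SE marginal-fidelity bounds and the 0.1 SMD threshold are
meaningful. Full-scale sizes (the source surveys' 63,522 / 15,771 and
m = 10) are one config edit away. All stage outputs are pure functions of
(config, master seed); stage seeds are derived once from the master seed.

## 10. Known limitations

* The simulator's dependence structure is main-effects logistic; synthesis
  quality on data with strong interactions is not measured here.
* One-vs-rest calibration with renormalization carries a small residual
  multiclass bias (the renormalizer is nonlinear); at n = 20,000 it stays
  inside 3·SE bounds but it is not exactly unbiased.
* The membership attack uses unweighted Hamming-style matching, not
  weighted record linkage; the non-member pool is drawn from the
  simulator's population generator.
* No survey design weights anywhere, matching the unweighted analysis being
  emulated.
* No differential-privacy accounting; the privacy evidence is empirical
  (attack-based) only.
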