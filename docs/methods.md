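# Methods

This note documents the statistical models and procedures implemented in
`pepanel`, the choices made where the design was genuinely open, and the
limits of what the synthetic-data tests demonstrate.

## Data model

The unit of measurement is a blood draw: patient id, gestational age (GA,
decimal weeks, validated to [4, 43]), group (control vs late-onset
preeclampsia, constant within patient), and a strictly positive abundance
per protein (relative fluorescence units, assumed already plate-normalized
by the assay provider). Classification operates on one row per patient per
gestational-age window; covariates (BMI, maternal age, parity, smoking,
case severity) live in a separate per-patient table and are used only by
the adjusted differential-abundance model — never by classification.

## Thresholding

Per protein, the cap is 2 × the 98th percentile of that protein's values
over all samples; values above it are replaced by the cap. The percentile
is computed with linear interpolation between order statistics (numpy's
default, the "type 7" convention) — a choice that had to be fixed because
several conventions exist; with hundreds of samples the difference is
negligible except in adversarial cases. Thresholding is per protein, not
global: a single percentile across reagents with scales differing by orders
of magnitude would be meaningless. The operation is order-independent and,
whenever the capped column's recomputed cap still clears every value,
idempotent.

## Normative trajectories and MoM

For each protein, control-sample log₂ abundance is modelled as

    y_ij = B(g_ij)ᵀβ + b_i + ε_ij,   b_i ~ N(0, σ²_patient),  ε ~ N(0, σ²_resid)

where B is a clamped cubic B-spline basis with 3 interior knots at the
25/50/75th percentiles of control GAs (only the knot *count* is canonical;
percentile placement adapts the basis to the visit distribution). The model
is fitted by REML via statsmodels `MixedLM`. Only a random intercept is
used: with 2–6 samples per patient, richer random structures (slopes) are
not identifiable. Two safeguards wrap the optimizer: a degenerate constant
column short-circuits to an exact flat fit with zero variances, and a fit
whose fixed-effect curve has residual sum of squares more than twice the
plain least-squares fit is treated as diverged (the L-BFGS path in
statsmodels can return a near-zero curve while reporting convergence) and
falls back to the fixed-effects-only fit with σ²_patient = 0, logged.

log₂ MoM of any sample (case or control) is log₂ abundance minus the fitted
fixed-effect curve at its GA — i.e. MoM is defined against the geometric
mean curve, the natural choice for a model fitted on the log scale. All
samples are normalized, including those beyond 36 weeks; the interval step
decides what is used. GAs outside the fitted control range are extrapolated
linearly from the boundary value and slope, with a warning. Consequences
verified by tests: control-set mean log₂ MoM ≈ 0 across 2-week GA bins, and
MoM invariance to rescaling any protein's raw column.

## Gestational-age windows

The canonical windows are [8, 16], (16, 22], (22, 28], (28, 32], (32, 36]
weeks — half-open on the left except the first, consistent with "16.1–22"
style labels at one-decimal GA resolution; together they partition (8, 36].
When a patient has several draws in one window, the default keeps the
sample closest to the window midpoint (ties → earlier GA): symmetric,
deterministic, and independent of the other patients. `earliest` and
`mean` (average of log₂ MoM vectors) collapse rules are available because
the right choice is not derivable from first principles; the per-window
patient counts are the only external constraint.

## LDA, LOOCV and pAUC

The classifier is the classical two-class linear discriminant: pooled
within-class covariance S (denominator n − 2), weights w = S⁻¹(μ₁ − μ₀),
score x ↦ wᵀx − ½wᵀ(μ₀+μ₁) + log(n₁/n₀); higher scores are more case-like.
A singular S is ridge-regularized by 10⁻⁶ × mean diagonal with a warning.
Leave-one-out scores pool each patient's score under the model fitted on
everyone else. Two numerical points:

- **Single-marker LOOCV is vectorised** over proteins via exact downdates of
  the class sums and pooled variance; a test confirms bit-level agreement
  with explicit refitting. This is what makes 100 bootstrap iterations over
  hundreds of candidates a seconds-scale operation.
- **The class-prior term is held constant across folds** at the full-data
  log(n₁/n₀). Priors shift every score of a given model equally and so can
  never move ROC-derived indices — but the *per-fold* prior depends on the
  left-out patient's class and, if pooled, biases the LOOCV ROC
  pessimistically (measurably: null AUC drifts to ≈ 0.30 at n = 60). The
  constant-prior convention restores the intended invariance; the analytic
  oracles (null AUC 0.5 ± 0.1; Gaussian Φ(2/√2) ± 0.02) pass under it.

ROC curves are empirical step functions (ties → diagonal segments,
integrated trapezoidally). pAUC is the trapezoidal area restricted to
FPR ∈ [0, 0.5], in raw units (perfect = 0.5, chance = 0.125); ranking and
the greedy gain rule both use raw units, matching the "+0.01" acceptance
increment. Operating points pick the most permissive threshold with
empirical FPR at or below the target, and achieved (not nominal)
specificity is reported — which is why tabulated specificities hover near
but not exactly at 0.90 for a 10% target. PPV/NPV derive from the implied
2 × 2 table at the window's observed prevalence.

## Panel construction

Candidates must change ≥ 10% in average abundance between groups
(|mean log₂ MoM difference| ≥ log₂ 1.1, boundary inclusive). Survivors are
ranked by single-marker LOOCV pAUC (ties broken by column order for
determinism). The panel starts with the top-ranked protein; each of the
next-ranked proteins, up to panel size 5, is added iff it raises the LOOCV
pAUC by ≥ 0.01. Only the top five ranked proteins are ever considered —
the literal reading of "increasing sets of up to five of the top proteins";
a rejected candidate does not stop the scan. An exhaustive subset search
(`best_subset`) exists for validation and confirms on constructed examples
that two independent, individually moderate markers are both selected when
their joint pAUC clears the gain rule. An empty candidate list yields an
explicit "no model" result, not an error.

## Bootstrap validation

Patients are resampled with replacement *within group*, preserving both
class sizes (stratification prevents degenerate single-class resamples).
The full selection procedure — filter, ranking, greedy growth — reruns on
each training resample (duplicates retained); the resulting model scores
the out-of-bag patients. MoM normalization is *not* redone inside the loop;
resampling operates on the transformed data. Resamples leaving fewer than 3
out-of-bag patients in either class, or on which no candidate survives the
filter, are redrawn and logged, so the summary always aggregates the
requested number of completed iterations (capped at 50× attempts).
Aggregates are means and 2.5/97.5 percentile intervals over iterations;
selection counts tally panel membership per protein. Everything is
deterministic given the seed.

The pipeline-level property this machinery exists to demonstrate: on pure
noise with hundreds of candidate proteins, the naive full-data LOOCV AUC of
the greedily selected panel is optimistic, while the in-loop bootstrap mean
stays in [0.4, 0.6] — selection bias made visible.

## Moderated t differential abundance

Per window and protein: least-squares fit of log₂ MoM on group plus (when a
covariate table is supplied) BMI, smoking, maternal age and parity.
Patients with missing covariates are dropped with a logged count (warning
if fewer than 80% remain); a rank-deficient design drops the offending
covariate column, never the group term. Residual variances s²_g (d df) are
shrunk by the classical empirical-Bayes scheme: under a scaled inverse-χ²
prior (d₀, s₀²), the posterior is s̃² = (d₀s₀² + d s²)/(d₀ + d) and the
moderated t uses d₀ + d degrees of freedom. The prior is estimated by
matching the mean and variance of log s² to the scaled-F sampling model
(digamma/trigamma closed forms, Newton inversion of trigamma); when the
spread of log s² does not exceed χ² sampling noise, d₀ = ∞ (complete
pooling). The implementation reproduces the R reference implementation
(limma's `lmFit`/`eBayes`) to 10⁻⁶ relative on a shared dataset, and the
d₀ → 0 / d₀ → ∞ limits recover the ordinary and fully pooled t exactly.
p-values are two-sided with BH adjustment *within* each window (per-window
significance reporting, not a global 5 × P family); significance requires
q < 0.25 and |signed linear FC| > 1.1, where FC = 2^b for b ≥ 0 and
−2^(−b) otherwise (so |FC| ≥ 1, negative = lower in cases). Cross-window
summaries clip displayed log₂ FCs at ±0.4.

## Enrichment

One-sided Fisher's exact test per term on (hits in significant set,
significant non-hits, background hits, background rest), background = the
annotated panel proteins (unannotated reagents can never be hits). BH
across tested terms; reported terms need ≥ 3 hits; enriched ⇔ q < 0.1.
Odds ratios are sample ORs with the Haldane 0.5 correction only when a cell
is zero. Enrichment results are only as good as the supplied annotation
map, which is an input: ORs are not comparable across annotation snapshots.

## Synthetic cohort generator

Abundance for patient i, protein p at GA g is
2^(f_p(g) + b_ip + δ_p(g)·[case] + ε): per-protein mean curves are flat or
random cubics in standardised GA (baseline log₂ ~ U(8, 14), matching the
dynamic range of fluorescence data), b_ip ~ N(0, σ²_patient) per
patient×protein, ε ~ N(0, σ²_resid), and δ_p(g) equals the configured log₂
effect inside its GA window, zero outside. Outliers multiply a value by
U(4, 10) (drawn from a separate seeded stream so base values are unchanged
by the outlier setting), guaranteeing the 2 × 98th-percentile thresholding
is exercised. Sampling schedules: per patient, draw 2–6 GAs uniformly in
8–40 weeks (default), or a 4-week visit grid with small jitter. Covariates
come from plausible marginals: BMI lognormal around medians 26.5 (controls)
/ 30.0 (cases), ~20% smokers, Poisson parity, mild:severe cases 48:28.

Default noise levels (σ_patient = 0.35, σ_resid = 0.25 log₂ units) were
fixed once so that the canonical benchmark signal — a 1.4-fold (log₂ 0.49)
case effect — yields a single-marker AUC near Φ(0.49/(0.43·√2)) ≈ 0.79,
i.e. the regime the pipeline is designed for: strong enough to be found,
weak enough that selection bias matters.

What the generator does **not** emulate: plate/batch structure, assay
chemistry, heteroscedastic or GA-varying residual noise, correlated protein
modules, informative visit schedules, or case-control differences in
sampling density. Tests passing on synthetic data therefore demonstrate the
correctness and calibration of the *procedures*, not robustness to those
real-data complications.

## Problem sizes and numerical conventions

Test and validation runs use scaled problem sizes chosen to keep the whole
suite desk-scale: synthetic panels of 200–500 proteins (vs 1,125 in a full
assay menu) for the bootstrap-recovery and null-calibration checks, B = 100
bootstrap iterations where calibration is asserted and 10–25 where only
mechanics are. The acceptance script uses 300 proteins and B = 100.
Tolerances follow the quantity's sampling noise: analytic oracles at 1e-6
or better, seeded statistical checks at 2 standard errors of the mean over
multiple seeds. Ridge 10⁻⁶, variance floors 10⁻¹², and a 10⁻¹² slack on
the inclusive 10%-change boundary are the only numerical fudge factors.

## Known limitations

- Interval collapsing rules other than the default change per-window
  membership and can move all downstream indices; only the default is
  benchmarked.
- The normative model assumes a common residual variance across GA; strong
  heteroscedasticity would mis-calibrate MoM tails (means stay unbiased).
- The greedy rank-order search examines only the top five ranked proteins;
  complementary pairs ranked lower are invisible to it (by design — it
  mirrors the published procedure; `best_subset` exists for comparison).
- Bootstrap redraw-on-failure slightly biases toward resamples with usable
  out-of-bag sets; with ≥ 20 patients per class the effect is negligible.
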