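# Methods

## Model

The classifier is a two-class support vector data description: one soft
hypersphere per risk class in the feature space induced by the RBF kernel
K(x, y) = exp(−‖x − y‖²/σ²). The joint objective R₁² + R₂² with
inside-own / outside-other constraints separates by sphere, so training
solves two independent "SVDD with negative examples" duals

    min_α Σᵢⱼ βᵢβⱼ K(xᵢ, xⱼ)    βᵢ = yᵢαᵢ,  Σᵢ βᵢ = 1,  0 ≤ αᵢ ≤ Cᵢ,

where y = +1 for the sphere's own class and −1 for the excluded class
(the linear dual term is constant under an RBF kernel and is dropped).

**Penalty assignment.** Own-class slack is penalised at C = 1 per sphere
(near-hard inclusion) and cross-class intrusions at 1/(νN_own), ν = 0.05.
This assignment was a genuinely open design choice — the opposite one
(own-class 1/(νN), exclusion 1) is equally expressible — and was settled
by the region structure it produces on overlapping classes: with soft
exclusion, the low-risk sphere covers essentially the whole low-risk
class *plus* a large share of high-risk patients (training membership FNR
≈ 0.56 on the default synthetic cohort), which is precisely the regime
the FNR-constrained reduction exists to correct; the opposite assignment
collapses both spheres onto small class-pure cores (≈ 74 % abstention,
FNR ≈ 2 %) and leaves the reduction with nothing to do. Both penalties
are exposed (`C1…C4` on `SVDDHyperparams`) if a user wants the other
regime.

**Solver.** Sequential minimal optimisation with maximal-violating-pair
selection on the KKT system 2f(xᵢ) ⋛ ρ (f = Kβ), analytic two-variable
updates with box clipping, stopping at a KKT gap ≤ 1e−6 (the `tol`
hyperparameter). The full kernel matrix is formed once and shared by both
spheres; training 1 400 points takes well under a second.

**Radius.** R² is the median squared centre distance of boundary support
vectors (duals strictly inside their box, relative margin 1e−6); the
median guards against a numerically degenerate single support vector. If
no boundary support vector exists, R² falls back to the maximum over
own-class points. Region membership uses d² ≤ R² + 1e−5: boundary support
vectors scatter around R² by the KKT gap, and the slack (10× the solver
tolerance) keeps them inside their own region. Classification: inside S₁
only → HIGH, inside S₂ only → LOW, otherwise UNCLASSIFIED (abstention);
abstained points stay in the accuracy denominator, so
sensitivity + FNR + fraction-unclassified = 1 holds exactly per class.

## FNR-constrained reduction

Only the squared radius of S₂ is shrunk, by a fixed factor (1 − 0.01)
per iteration, with centre and duals frozen; this makes the FNR trace
provably non-increasing and nests the reduced region inside the original.
The controlled quantity is the fraction of high-risk *training* points
inside S₂ (membership, regardless of S₁) — the monotone quantity the
radius directly controls; the confusion-matrix FNR (classified LOW) is
bounded above by it, so terminating at τ also controls the reported rate.
The procedure stops at FNR ≤ τ = 0.08 and raises (with its full trace)
if low-risk coverage falls below the 0.35 floor first. On the default
synthetic cohort it terminates after ~21 steps at coverage ≈ 0.44.

## Counterfactual search

Candidates are the first L points of the unscrambled Halton sequence
(first-d primes bases, the index-0 all-zero point skipped) over the
7-dimensional controllable subspace of the scaled unit cube, per factual:
age and sex are copied from the factual, and hypertension is enumerated —
locked at 1 for hypertensive factuals under the default `chronic_lock`
policy, both values (pool doubled) for non-hypertensive ones. A candidate
is retained iff it is inside S₂ (reduced, if applicable) and outside S₁
under the same membership rule as the classifier, which makes validity
1.0 a theorem rather than an observation. The returned counterfactual
minimises the Euclidean distance over *all* scaled features (fixed
coordinates contribute 0; an HTN flip contributes 1 to the squared
distance and is thereby naturally discouraged); ties break toward the
lowest Halton index, then toward the factual's own HTN value. L defaults
to 10 000 in `SearchConfig`; the packaged experiments use L = 2 000,
which at 7 controllable dimensions already leaves the returned distances
insensitive to further refinement at the reported 2-decimal precision.

Because the RBF kernel factorizes over disjoint coordinate blocks
(K = K_ctrl · K_fixed) and all factuals share the same Halton grid, the
(L × n_support) kernel block over controllable dimensions is computed
once per sphere and reused across factuals; per factual only an
n_support-length fixed-block factor is formed. An independent naive
implementation (explicit per-candidate loop, kernel rows recomputed from
scratch) lives in the test suite and must return identical
counterfactuals.

A similarity threshold ε (maximum admissible scaled distance) exists on
`SearchConfig` but is disabled by default; distances are reported
instead, as no defensible universal cutoff exists.

## Metrics and statistics

Availability = returned / requested; validity = fraction of returned
counterfactuals classified LOW; actionability = mean per-pair fraction of
fixed features (age, sex) unchanged, with permitted HTN 0→1 flips tallied
separately (HTN is conditionally fixed and excluded from the
denominator); similarity = scaled distance / √n_features, summarised by
the mean and the 2.5th–97.5th percentile interval of the per-pair
distribution (an interval of the distribution, not a standard error —
the spread of individual recommendations is the quantity of interest);
discriminative power = mean 5-fold stratified CV accuracy of a 5-NN
classifier (Euclidean, scaled space) separating counterfactuals from real
high-risk points, fold shuffling seeded.

Biomarker changes Δu = u* − u are summarised per patient group
(female/male × HTN/noHTN, determined by the factual) as median (P25; P75)
with linear-interpolation percentiles. Tests: Lilliefors for normality of
each change distribution; two-sided Wilcoxon signed-rank (zeros dropped,
exact null for small tie-free samples, tie-corrected normal approximation
otherwise) for within-group shifts; two-sided Wilcoxon rank-sum
(Mann–Whitney) for between-group contrasts. Bonferroni families default
to the 7 biomarkers within one group (paired tests) and within one sex
(between-group tests); rejection at p ≤ α/m, α = 0.05. Family scope is an
assumption, not a derived fact, and is confined to the `characterize`
wrapper — the individual tests report raw p-values.

## Synthetic cohort generator

The generator emulates the population structure the method assumes, not
any particular dataset: a balanced two-class cohort with overlapping
class-conditional biomarker distributions. Per class, numeric features
are independent truncated normals clipped to the schema plausibility
bounds (FBS 2–20 mmol/L, BMI 12–70 kg/m², sBP 70–250 mmHg, HDL 0.3–4,
LDL 0.3–8, TG 0.2–15, total cholesterol 1–12 mmol/L, age 30–110 y).
Demographics follow a typical primary-care T2DM screening population:
high-risk class 54.1 % female, age 57 ± 13 (F) / 58 ± 11 (M); low-risk
class 61.3 % female, age 58 ± 11 (F) / 60 ± 11 (M). Class-conditional
FBS means straddle the clinical prediabetes threshold of 5.6 mmol/L
(6.3 ± 1.2 high vs 5.0 ± 0.7 low); the remaining means/SDs are documented
assumptions in `default_t2dm_config` (higher BMI, sBP, TG, lower HDL in
the high-risk class). Hypertension prevalence is 0.45 (high) vs 0.25
(low), keeping non-hypertensive groups larger than hypertensive ones in
both classes. An `overlap_scale` multiplier on all SDs moves the cohort
between a near-separable and a heavily overlapping regime.

What the generator does **not** emulate: between-biomarker correlations
(independent draws by default; a Gaussian-copula hook accepts a
user-supplied correlation matrix), longitudinal averaging of repeated
readings, missingness, or heavy-tailed laboratory error. Passing tests on
synthetic cohorts therefore demonstrate the machinery's correctness and
the method's qualitative behaviour under controlled overlap — not
clinical performance on real EMR data.

## Problem sizes

Packaged experiments run at 1 000 patients per class (700/class
training after the 70/30 split) with L = 2 000 candidates — sizes at
which every reported quantity is stable across seeds while a full
pipeline run completes in a few seconds. The generator's
`default_t2dm_config` defaults to 2 791 per class, the scale of the
motivating study population.

## Known limitations

* Radius-only reduction cannot reshape S₂; a centre-adaptive variant
  could reach the same FNR with higher coverage but loses the
  monotonicity guarantee.
* The Halton discretization treats the controllable subspace as a box;
  no causal or physiological coupling between biomarkers is enforced
  (e.g. total cholesterol is sampled independently of LDL/HDL/TG).
* Exactly one counterfactual is returned per factual; diversity is out
  of scope.
* With identical class distributions the spheres overlap almost totally
  and most points are abstained on — the method presumes classes that
  are at least partially separable in the chosen biomarkers.
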