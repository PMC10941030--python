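# Methods

## The assessment being modelled

A gaming session consists of four sequential games steered by plantar
pressure, played within a 15-minute budget: Apple-Catch (AC, 14 tasks,
forefoot-controlled carriage, reaction and precision), Balloon-Flying (BF,
altitude from the forefoot pressure differential between feet, bilateral
coordination), Cross-Pressure (CP, hold a prescribed pressure band on an
indicated foot region for a set duration, 25 s timeout per task) and
Island-Jump (IJ, produce a peak pressure inside a target band; failed
attempts repeat). Pressures come from eight force-sensing resistors per
insole (heel, lateral arch, metatarsals 1/3/5, hallux, toes, plus one
auxiliary sensor whose region is configurable), quantized at 3.4 mbar in
[250, 7000] mbar and normalized per sensor to [0, 1] by a rest/maximum
calibration. The default game order is AC, BF, CP, IJ and is configurable.

Per-task *primary* features (reaction time, catch success, positional
error, hold time, timeout flags, attempts, …) are aggregated over *task
combinations* — the set of left-foot-controlled tasks of a game (TCL), the
right-foot set (TCR), and bilateral sets (TCB) — into sum, mean and sample
SD *secondary* features. The default catalogue (4 base features per game)
yields 168 primary + 84 secondary = 252 game features; the published
catalogue is far larger (thousands of parameters), so the catalogue here is
parameterized rather than enumerated to a fixed count, and counts of
significant features are not comparable with the published ones.

## Synthetic cohort

The generator's defaults are the study conditions: n = 261 patients with
diabetes aged over 50, in four groups −PNP−CD / +PNP−CD / −PNP+CD / +PNP+CD
with exact quotas 80/92/28/61. Covariates are drawn per group from
moment-matched distributions (normal for age — truncated above 50 —, weight
and BMI; log-normal for diabetes duration; Bernoulli for gender and
diabetes type) using the published group medians/IQRs and proportions, with
σ = IQR/1.349 for the normal case and σ = asinh(IQR/2m)/0.6745 for the
log-normal. Education years follow a 60/40 two-point mixture (≤ 12 vs > 12
years); the source reports no education distribution.

Latent traits are a mechanistic stand-in for the capabilities the games
probe. Each participant draws latent cognition and neuropathy variables
(unit-variance normals shifted by group), which drive:

| trait | healthy base | impairment effect (default) |
|---|---|---|
| reaction latency mean | 0.50 s | +0.25 s if CD |
| reaction latency SD | 0.08 s | +0.04 s if CD |
| decision-error probability | 0.03 | +0.10 if CD |
| pressure-control noise SD | 0.020 | +0.04 if PNP |
| sensation threshold | 0.05 | +0.10 if PNP |
| fatigue slope | 0.004 s/task | +0.004 s/task per condition |

Clinical scores are drawn around latent-linked means (e.g. MoCA mean
26.5 + 1.2·cognition) and rejection-sampled (cap 1000, means clamped into a
label-compatible window so the loop terminates for extreme draws) until the
diagnostic rules — PNP ⇔ NDS ≥ 6 or (NDS ≥ 3 and NSS ≥ 5); CD ⇔
education-adjusted MoCA < 26, one point added for ≤ 12 education years,
capped at 30 — reproduce the group label exactly. Severity bands: NDS
3–5/6–8/9–10 and NSS 3–4/5–6/7–10 for mild/moderate/severe.

## Session simulator

The motor model is a first-order lag toward the target pressure (time
constant 0.3 s) starting after the reaction latency; latency is drawn per
task and shifted by the fatigue slope times the task position. Control
noise is a stationary Ornstein–Uhlenbeck process (correlation time 0.5 s)
rather than white noise — physiological pressure error wanders slowly,
which is what makes multi-second band holds possible at realistic noise
levels. A decision error (probability per task) models acting on the wrong
foot/region and costs a 1 s recovery delay. In CP, a band narrower than
the sensation threshold inflates the effective noise by half the
imperceptible remainder; a *non-finite* threshold is treated as "indicator
not perceived at all", which forces the exact 25 s timeout. In IJ the peak
pressure error scales with noise plus a quarter of the sensation threshold,
and attempts repeat up to a cap of 5 per island (the source states
repetition but no cap). BF maps the balloon altitude to
0.5 + (mean left forefoot − mean right forefoot)/2 with a collision
tolerance of 0.15 normalized units.

All emitted pressures are round-tripped through the 3.4 mbar sensor grid
(nearest-grid, ties to even) and re-normalized. The default simulation
sampling rate is 50 Hz (configurable to the device's 200 Hz); features are
sampling-rate-invariant up to one sample period by construction. With all
trait dispersions at zero every task succeeds and the session completes in
about 150 s, well inside the 900 s budget.

## Feature extraction

Reaction time is the first crossing of 0.2 normalized pressure on a target
sensor after stimulus onset (the threshold is a configurable choice — above
the noise floor, far below typical targets; the source states none).
Hold-stability SD is the sample SD of pressure over the valid hold window;
timeout flags are 0/1; values undefined for a trace (reaction time on a
timeout, SD of a single member) are missing. Aggregation over a TC uses
non-missing members only; the SD is the sample (n−1) SD and is missing with
fewer than two values. Preprocessing drops columns missing in more than
20% of rows and constant columns, then median-imputes the remainder; the
six IRP columns (gender, age, weight, BMI, diabetes type, diabetes
duration) are always retained.

## Statistics

Group comparisons gate on Shapiro–Wilk normality at α = 0.05 per group:
t-test / one-way ANOVA when all groups pass, Mann–Whitney U /
Kruskal–Wallis otherwise (exact Mann–Whitney p for tie-free samples of
≤ 8 per group, normal approximation with tie correction otherwise);
chi-square for categorical variables (Yates correction off by default for
2×2). Summaries report mean (SD) under normality and median (IQR = Q3−Q1,
linear-interpolation quantiles) otherwise. Holm–Bonferroni is the textbook
step-down with monotonicity enforcement and capping at 1. Correlation
auto-selects Pearson vs Spearman by the same normality gate, with pairwise
deletion of missing values.

## Matching and association

Cardinality matching selects maximum-cardinality equal-size subsets of the
two outcome groups subject to |SMD| ≤ 0.1 for each of the six profile
covariates, with an exact count constraint on diabetes-type levels (the
published post-match type-1 counts are exactly equal, which suggests such a
constraint). The SMD denominator is frozen to the pre-match pooled SD —
the conventional reporting choice, and what keeps the balance constraints
linear in the selection indicators:
|Σ_A z x − Σ_B z x| ≤ 0.1·sd_pool·n_A(x). The integer program is solved
with HiGHS (`scipy.optimize.milp`); a deterministic greedy fallback
(iteratively drop the worst-imbalance member of the larger group) is
flagged in the result status.

Odds ratios use the 2×2 cross-product with the Woolf log-SE interval and a
0.5 continuity correction only when a zero cell occurs (flagged). Logistic
models are maximum-likelihood fits (IRLS via a binomial GLM) with Wald 95%
CIs; perfect separation is detected and raised, not silently reported. The
four-model layout is: Model 1/2 univariate/adjusted on the full cohort,
Model 3/4 the same on the matched subcohort; categorized exposures use the
first stage as reference. Wald/Woolf intervals are a deliberate, documented
approximation — the published univariate interval is close to but not
exactly Woolf, and the published *adjusted* ORs depend on individual-level
covariates that are not available, so they are not reproduction targets.

## Classification

For each contrast against the unimpaired group (−PNP−CD): Pearson
correlation pruning removes game features until all pairwise |r| ≤ 0.5
(greedy: of the worst pair, drop the member with the larger mean absolute
correlation; ties drop the later catalogue column; IRP columns exempt);
features are then ranked by family-specific importance (absolute
standardized coefficients for linear families, impurity-based split gain
for tree families) averaged over an internal stratified 5-fold split, and
the top ten become the final predictors. Ranking and selection run on the
full training set before cross-validation, mirroring the described order of
the original analysis; this induces selection optimism, which is why the
comparison of interest (IRP-only vs IRP+game under the *same* protocol)
and the label-permuted null control are the supported claims — absolute
AUCs are not comparable with values obtained under nested selection.

Evaluation is stratified 10-fold cross-validation repeated 10 times, fully
seeded. The reported AUC-ROC is the mean of per-repeat AUCs (per-repeat
out-of-fold scores pooled first); the AUC itself is the Mann–Whitney pair
count (concordant + half ties over positive×negative pairs).
Sensitivity/specificity come from the Youden-optimal threshold
(max sens + spec − 1, ties to the lower threshold) on the scores pooled
over all repeats — the operating rule of the original report is unstated,
so this is a package choice. Default families are elastic-net logistic
(l1_ratio 0.5, C 1) and gradient boosting (100 trees, depth 2); random
forest, linear SVM and ridge logistic are available through the same
registry.

## Orchestration and seeding

`run_all` executes cohort → sessions → features → statistics → matching →
three contrasts → feature screen, writing CSV/JSON artifacts and a manifest.
A single master seed fans out into per-stage seeds via
`numpy.random.SeedSequence.spawn` in a fixed stage order (all below 2³¹),
so identical config + seed reproduce byte-identical CSV artifacts. The
feature-group screen matches each impaired group against the reference on
the six covariates, then compares every non-constant game feature between
the matched groups with the normality-gated test and Holm adjustment within
the subcohort.

## Problem sizes and what the tests show

The shipped checks run the full pipeline at the study scale (n = 261,
quotas 80/92/28/61, 50 Hz simulation) over a handful of seeds, and the
acceptance script uses three study replicates; associations are checked by
parameter recovery at n = 2000 and Woolf coverage over 500 simulated
tables. Passing them establishes that the *pipeline* is correct and
internally consistent — that planted impairment effects are recovered, that
nulls are null, and that the worked-example arithmetic matches the
published counts. It does not establish clinical validity: the synthetic
generator encodes simple mechanistic links between impairment and game
behaviour (monotone latency/noise shifts, stationary noise, no learning or
training effects, no dropout, no device artifacts), so real-data effect
sizes, AUCs and significant-feature counts will differ.

## Known limitations

- The latent-trait model is deliberately minimal; it produces strong,
  well-separated group differences under the defaults, so absolute
  synthetic AUCs (≈ 0.99 for profile+game models) exceed what clinical
  data yielded and should be read only through the IRP vs IRP+game
  comparison.
- The eighth sensor's anatomical region is unspecified in the source and is
  labelled `aux`.
- 14 incomplete sessions in the original study arose from device/usability
  issues; the simulator only produces incomplete sessions via the time
  budget, so the exclusion path is exercised by construction in tests
  rather than emergent.
- The exact preprocessing that reduced the published catalogue to
  "independent" features is unspecified; here it is the documented
  drop/impute pass plus the |r| > 0.5 pruning.
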