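# Methods

This note records the models implemented in `dfckit`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Sliding-window dFC

A participant-timepoint is a regions × volumes matrix (AAL-90 order, 180
volumes at TR = 2.1 s in the reference design). Windows of `length_volumes`
L = 28 advance by `step_volumes` S = 5; only fully contained windows count
(no padding), so a T-volume series yields ⌊(T − L)/S⌋ + 1 windows — 31 for
T = 180. Window starts are reported 1-based; internally indexing is 0-based.

Within each window the absolute Pearson correlation matrix is computed
(standard Pearson, which demeans per window implicitly; no Fisher
z-transform — the statistic is built on raw absolute correlations). The
per-connection dFC is the coefficient of variation across windows with the
*sample* standard deviation (denominator W − 1, the unbiased-variance
convention). The absolute value is applied per window *before* the SD/mean
step.

Numerical conventions:

* correlation matrices are symmetrized ((C + Cᵀ)/2) and clipped to [−1, 1]
  before the absolute value, so symmetry and boundedness hold exactly;
* a connection that is exactly constant across windows gets dFC exactly 0
  (the two-pass variance would otherwise leave a ~1e−17 residue);
* connections whose mean windowed correlation falls below `mean_floor`
  (default 1e−6) are masked as NaN rather than divided through, and masked
  entries are excluded from all averages;
* a region with zero variance inside any window is an error naming the
  region and window, not a silent NaN.

Network summaries (`network_dfc`) average the member-to-rest connections of
the DMN or FPN — all 90 regions minus the members count as "rest",
subcortex included, within-network pairs excluded — m(N − m) connections
for m members. `whole_brain_dfc` averages all N(N − 1)/2 unique pairs.

The AAL-90 → Yeo-7 assignment ships as an editable CSV fixture
(`region_id,name,cortical,network`): 90 regions, 78 cortical, networks
collapsed to {DMN, FPN, OTHER_CORTICAL} plus SUBCORTICAL, because only DMN
and FPN summaries are extracted downstream. The assignment follows the
published AAL-to-Yeo correspondence but any mapping with the same schema
can be swapped in; nothing is hard-coded.

## Surrogate null model

`phase_randomize` draws one phase offset per positive frequency, uniform on
[0, 2π), and applies the *same* offsets to every region's rFFT; DC — and
the Nyquist bin for even-length series — keep phase 0 so the inverse
transform is real. Because all regions share the rotation, every
cross-spectrum is unchanged, hence the full-length correlation matrix and
each per-region amplitude spectrum (and therefore variance and circular
autocorrelation) are preserved to machine precision, while any
time-localized coupling structure is destroyed. Independent per-region
phases would *not* preserve stationary correlation and are deliberately not
offered.

Ensembles of K copies (default 20) derive copy k from the sub-stream
`SeedSequence(seed, spawn_key=(k,))`, so regeneration is bit-identical and
parallel-safe. The observed whole-brain dFC is compared to the
per-participant surrogate mean with a two-sided paired t-test (df = n − 1;
101 participants give df = 100). The degenerate all-zero-difference case
returns t = 0, p = 1; a constant non-zero difference is an error.

## Cognition: normative change scores

Raw scores are z-standardized on the norm group's (default NC) baseline
mean and SD. Trail-Making-B times are sign-flipped at standardization so
lower z uniformly means worse performance; raw seconds are never compared
across tests. Follow-up z is predicted from (baseline z, age, IQ) by OLS
fitted in the norm group only (statsmodels), and the residual
(observed − predicted) is the change score. The norm group is configurable
and may include participants without imaging, so the norm n can exceed the
imaging sample. Missing data are handled by listwise exclusion per test
with logged participant ids; no imputation.

Group comparisons use one-way ANOVA on the residuals and pooled-SD effect
sizes, ES = (m₁ − m₂)/s_pooled with the (n−1)-weighted pooled SD. Reported
effect sizes are rounded half-away-from-zero to 2 decimals; full precision
is kept internally.

## Repeated-measures models

With exactly two within-subject levels the repeated-measures model
decomposes exactly: between-subject terms are tested on per-subject means
across time, terms involving time on per-subject differences (follow-up −
baseline), with the time main effect as the intercept of the difference
model. Both blocks share one between-subject design: sum-to-zero (effect)
coded group, the grand-mean-centered continuous dFC-change predictor, their
interaction, and centered age/IQ covariates. Each term gets a
Type-III-style F-test — full model versus the model without that term —
which is the appropriate convention for unbalanced groups and reproduces
the output of full-factorial ANCOVA software; the engine is an explicit
least-squares implementation and is verified in the tests against an
independent statsmodels Type-III route and (for the covariate-free case) a
long-format GLM with subject indicators and pingouin's mixed ANOVA.

Conventions and edge cases:

* the one-value-per-participant dFC change is modelled as a between-subject
  continuous predictor that may interact with group and time;
* dependent scores are z-anchored on the NC baseline before fitting (an
  affine step; F statistics are invariant, but per-group slope signs become
  comparable across tests, including the TMT-B flip);
* significance is `p < alpha` strictly (p = α is not significant), with
  α = 0.01 as the default threshold; no further multiplicity correction
  is applied to the model terms;
* a rank-deficient design (e.g. a constant Δ-dFC) is an error naming the
  collinear term; a response with exactly zero residual variance yields
  F = 0, p = 1 when there is nothing left to explain, and an error if a
  term would fit it exactly;
* residual df are n − p in both blocks (p = 8 with the full design), so a
  101-participant complete-case cohort gives F(·, 93). Note the two blocks'
  error degrees of freedom are reported separately and are not pooled.

Per-group slopes of cognitive change on dFC change (`group_slopes`) are
plain per-group OLS fits, meant for visualizing slope inhomogeneity; the
inference about it is the group × Δ-dFC interaction.

## Synthetic cohorts

The generator emulates the measured inputs of the three-group longitudinal
design so every stage is testable without data. Defaults are the study
conditions: group sizes 34/32/35, 90 regions, 180 volumes, TR 2.1 s, age ~
Normal(50, 9), IQ ~ Normal(104, 13).

**Signal model.** Three latent unit-variance AR(1) drivers (DMN, FPN,
other; AR coefficient 0.3 as a minimal autocorrelated BOLD stand-in) share
a common AR(1) global component with correlation `inter_network_coupling`
(default 0.85). Region r follows its driver with coupling
w_r(t) = w₀ + a·sin(2πt/P_r + φ_r), with base coupling w₀ = 0.5, period
P_r uniform in 40–80 volumes, random phase, and modulation depth a (the
dynamic ground truth; a = 0 is a genuinely static cohort). The region
series is w_r·s_net + √(1 − w_r²)·ε_r with AR(1) noise, standardized per
region. Sinusoidal modulation (rather than regime switching) keeps the
ground truth a single analytic depth parameter. The strong shared global
component is what gives member-to-rest connections a non-zero stationary
correlation — with independent drivers, between-network correlations are
pure noise and network-level dFC cannot respond to modulation at all; 0.85
corresponds to rsfMRI without global-signal regression and makes the mean
network dFC increase monotonically over depths 0–0.4 with margins
resolvable by ~150 Monte-Carlo seeds.

**Cognition model.** Baseline z is drawn around group means (SD 1);
follow-up z = group intercept + group slope × standardized *true* change in
modulation depth + β_age·(age − 50) + β_IQ·(IQ − 104) + noise. Per-
participant depth jitter (SD 0.05) makes the slope identifiable within
groups. Because the pipeline's measured Δ-dFC is only a noisy proxy of the
true change, estimated slopes from the full BOLD route are honestly
attenuated. Raw scores are emitted on realistic scales (HVLT-R ≈ 26 ± 4.5
words; TMT-B ≈ 75 ± 25 s, higher = worse) so the standardization and
sign-flip paths are exercised. `SimulationConfig.sign_reversal(beta)`
configures the opposite-sign slope pattern (+β untreated patients, −β
chemotherapy group and controls).

`simulate_cohort_scores` is a fast score-level variant for calibration
studies: dFC summaries come from a linear measurement model
(dfc = 0.2 + 0.3·depth + N(0, 0.02)) and cognition couples directly to the
standardized generated dFC change, so the regression ground truth is exact
and thousands of replicates are cheap.

All randomness flows from one master seed: demographics/cognition use spawn
key (0,), the series of participant i at timepoint t uses spawn key
(1, i, t), surrogate copy k uses (k,).

**What the generator does not emulate** — hemodynamic convolution,
physiological noise, scanner drift, head motion, preprocessing artifacts,
site effects, non-sinusoidal (e.g. state-switching) dynamics, and
heavy-tailed score distributions. Passing tests therefore demonstrate the
*statistical machinery* (calibration, power, invariances, oracle
agreement) under a clean generative model, not robustness to real
acquisition artifacts.

## Calibration and power checks

The statistical tests are checked empirically at the study's group sizes:

* **Type-I calibration.** Under the full-null score-level cohort, each of
  the 11 ANCOVA terms is tested at α = 0.01 over 500 replicates. Each
  term's rejection count is compared to Binomial(500, 0.01) with an exact
  two-sided binomial test at a Šidák-adjusted level (family of 11
  simultaneous checks held at 5%); without the adjustment the joint
  false-alarm probability of eleven 95% interval checks would be ≈ 20%.
* **Power.** With slopes ±0.8 noise-SD units per SD of dFC change
  (opposite signs across groups) and n = 34/32/35, the group × Δ-dFC
  interaction at α = 0.01 is detected in > 80% of 200 replicates
  (observed ≈ 0.97).
* **Surrogate calibration.** Under static coupling (a = 0) the paired
  surrogate test's rejection rate at α = 0.05 stays inside the exact
  binomial 95% interval over 200 small cohorts.
* **Monotonicity.** Mean DMN dFC increases strictly over depths
  {0, 0.1, 0.2, 0.3, 0.4} with 150 paired seeds per level (the same seeds
  are reused at every depth, so the contrast isolates the modulation).

Reduced problem sizes are used where the full scan geometry is not itself
under test: the surrogate calibration runs 8 regions × 80 volumes with
20-volume windows and K = 6 copies; monotonicity and cohort-level surrogate
tests use 12–20 region parcellations. The surrogate preservation properties
are checked at the full 90 × 180 geometry.

## Known limitations

* The published group-level F statistics of the reference analysis are not
  reproducible here: the underlying fMRI data are not public, and the
  pipeline's error df at n = 101 complete cases is 93, while the reference
  reports 92 (consistent with one additional excluded case or term that the
  source text does not pin down). The deterministic arithmetic (window
  counts, timing, df of the paired test, effect-size recomputation) is
  reproduced exactly.
* One printed effect size in the reference (−0.47 for the patient-group
  comparison) is not recoverable from its rounded group statistics
  (recomputation gives ≈ −0.57); it was presumably computed on unrounded
  data and is not used as a check. The chemo-vs-control value (−0.06) is.
* The two-timepoint decomposition is exact but does not generalize to ≥ 3
  within-subject levels; no sphericity machinery is included because two
  levels make it moot.
* NIfTI/voxel-level input, atlas warping, and motion estimation are out of
  scope; the expected input is already-parcellated region time series.
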