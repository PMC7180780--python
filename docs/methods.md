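# Methods

## Problem setting

Oscillometric blood-pressure devices estimate systolic and diastolic pressure
(SBP, DBP, mmHg) from features of the cuff-oscillation waveform.  Validation
protocols compare a device against auscultatory references taken by trained
observers.  The package models the estimation chain end to end: repeated
measurements per subject, bootstrap enlargement of the tiny per-subject
sample, a boosted neural-network regressor, and uncertainty statements (GUM
quantities, confidence intervals, normality checks, device grades) attached
to the estimates.

## Synthetic cohort generator

The generator emulates the measurement protocol, not the physics.  Per
subject it draws a latent true pressure pair from a population distribution,
perturbs it per sequence with within-subject variation, produces two rounded
observer readings per sequence, averages them into the reference, and emits
features as an affine map of the sequence's true pressures plus Gaussian
noise.

Defaults and rationale (all pressures mmHg):

| parameter | default | why |
|---|---|---|
| subjects | 85 | the protocol cohort size the pipeline targets |
| population SBP | N(115, 12) | brackets typical normotensive CI centres (~107–112) |
| population DBP | N(67, 9) | likewise (~65–69) |
| within-subject sd | 2.5 | matches the observed spread of five repeats (raw sds ~2.2–2.4) |
| observer sd | 1.0 | two observers disagreeing by 0–2 mmHg, as auscultation typically does |
| feature dimension I | 12 | the reference network's input width; configurable because the named waveform features enumerate only 8–10 columns and the remainder is unspecified |
| feature noise sd | 3.0 | keeps features informative but not trivially invertible at the default loading scale |

Latent true pressures sit on the integer mmHg grid (auscultatory references
resolve to manometer ticks), so the fully noise-free configuration reproduces
`ref == true` exactly.  Observer readings are rounded to whole mmHg;
references may be half-integers.  The ~1.5-minute delay between wrist and arm
measurements in the real protocol is absorbed into the within-subject term,
not modelled as a drift.

What the generator does **not** emulate: raw cuff-pressure waveforms,
Korotkoff sounds, arrhythmia or motion artefacts, age/sex structure, feature
distributions with heavy tails, or any nonlinearity between features and
pressures.  Tests passing on this cohort therefore demonstrate correctness of
the machinery and recoverability of an affine signal under Gaussian noise —
not clinical performance on real waveforms.

## Bootstrap artificial features

Per subject and replicate, one index multiset of the five sequences is drawn
and shared by all feature columns *and* both targets ("synchronous"
resampling), so artificial features remain paired with artificial targets and
cross-feature dependence survives.  Resampling each column independently is
available behind a flag but breaks the feature/target pairing that regression
needs; the notation of the original algorithm is per-feature, and this is a
deliberate, documented deviation.  Bias is the plug-in form (mean of
replicate means minus sample mean); the bootstrap SE uses the 1/(B−1)
divisor.  One master seed spawns per-subject child streams, so enlarging the
cohort leaves existing subjects' replicates unchanged.

## Lilliefors test

The statistic is the sup-distance between the empirical CDF and
Φ((x−x̄)/s) with x̄, s (ddof = 1) estimated from the sample.  Critical values
come from a Monte-Carlo table frozen into the package (10⁵ null replicates
per sample size, fixed build seed, n = 4…500 at α ∈ {0.20, 0.15, 0.10, 0.05,
0.01}); published tables are too sparse in n.  The table is forced monotone
non-increasing in n (true of the exact values; removes residual simulation
jitter), interpolated linearly in cv·√n against 1/√n between grid points and
linearly across α; beyond n = 500 the asymptote cv·√n of the largest grid
point carries over, which at α = 0.05 tracks 0.886/√n (0.0889 at n = 100).
P-values are simulated from the null at the sample's n (default 10⁴
replicates) and capped at 0.5, the conventional reporting ceiling for this
test; the reject/accept decision uses the frozen table, never the simulated
p, so it is deterministic.  Kurtosis is reported non-excess (Gaussian
reference 3).

## Weak learner

A multilayer perceptron with logistic hidden units and a linear two-unit
output; a logistic output could not represent unbounded mmHg targets.
Defaults follow the reference configuration: three hidden layers of 32
units, weight learning rate ζ = 0.001, bias rates 0.01, momentum η = 0.9,
10–50 epochs, weights initialised Uniform(−1, 1).  (The source description
wavers between two and three hidden layers; three is the default, and the
width is configurable.)  Inputs and targets are standardized on training
statistics frozen for prediction.  The cost is the batch-mean of the summed
per-target squared error; the update is momentum gradient descent,
v ← ηv − ζ∇L, θ ← θ + v.  Analytic gradients are validated against central
finite differences (relative error < 10⁻⁴) in the suite.  Divergence (cost
leaving the finite range) raises with the epoch index.

Pre-training: a Gaussian–Bernoulli RBM links the standardized real-valued
input layer to the first binary hidden layer, Bernoulli–Bernoulli RBMs stack
above, each trained with CD-1.  `bagged_init` pre-trains K_pre stacks on
bootstrap resamples of the rows and combines them **element-wise by
averaging**: the original formulation writes a sum, but a sum scales first-
layer activations by K_pre; the mean keeps them on the single-learner scale.
This discrepancy is flagged here rather than silently resolved.

## Boosting loop

Weights live over all L artificial rows; each round trains on a multinomial
resample of M rows (M = L by default) — the alternative of weighting the
loss without resampling is exposed as the `M` parameter plus factory choice.
Relative errors ε_m use the squared Euclidean norm over both targets,
normalised by the round's maximum.  Feedback: round 1's estimate columns are
the predictions of a baseline learner trained on the features alone (the
recursion needs a defined, reproducible start; the original leaves round-1
values unspecified); thereafter the feedback is the weighted median of the
rounds fitted so far, the same rule used at prediction time, so training and
inference see the same feedback distribution mechanism.

Degenerate rounds: ε_max = 0 or ε̄ = 0 assigns the floor β = 10⁻¹⁰ (maximal
confidence) and stops boosting; ε̄ ≥ ½ discards the round and resamples, up
to three retries (the AdaBoost.R2 convention).  β ≥ 1 would carry a
non-positive log-weight and receives zero weight in the median; if every
learner is weightless the ordinary median is used.  The weighted-median
tie-break follows the infimum definition exactly: ascending stable sort,
first prediction whose cumulative log(1/β) reaches half the total (for even
counts with equal weights this picks the lower bracketing order statistic,
not the midpoint).

**Observed limitation.**  The hoped-for property that boosting lowers
held-out SDE relative to a single weak learner at a matched total epoch
budget did **not** hold in our simulations (10 seeds, matched-total and
matched-per-learner budgets, raw and bootstrap-augmented cohorts,
homoscedastic and heteroscedastic noise): the ensemble was at best on par.
Two mechanisms act against it — the weight distribution concentrates on
noisy rows (the classical AdaBoost.R2 noise sensitivity), and the test-time
feedback starts from the baseline learner and inherits its held-out error.
The ensemble's absolute performance on the synthetic cohort is nevertheless
comfortably inside the AAMI bounds; only the comparative claim is
unsupported, and the suite asserts the exact bookkeeping invariants instead.

## Confidence intervals and uncertainty

The bootstrap interval is **parametric** exactly as defined: an n×B matrix
of Gaussian draws μ̂ + σ̂Z, column means, ascending sort, percentiles at α
and 1−α (level 1−2α; defaults B = 100, α = 0.025).  A nonparametric variant
(resampling the five estimates) sits behind a flag.  The percentile index
rule is linear interpolation between the closest order statistics (index
q·(n−1)), fixed so endpoints are bit-stable.  The "Monte-Carlo" interval is
the closed form μ̂ ± Φ⁻¹(0.975)·s/√n with s using the n−1 divisor; the name
is kept for traceability although no sampling is involved.

Both constructions use the Gaussian 1.96 quantile with an *estimated* sd, so
at n = 5 their true coverage is P(|T₄| ≤ 1.96) ≈ 87.9 %, not the nominal
95 % — a property of the methods as defined, reproduced (not corrected) here
and verified in the suite against the t-based closed form.  Simulation also
shows the two widths agree within ~4 % on average at n = 5, B = 100 (the
bootstrap percentile is very slightly narrower through the inward bias of
sample quantiles), so neither method is systematically tighter.

GUM quantities: u = σ̂/√n; u_c is the root-sum-of-squares of the random
component, the bias, and — in device-level reports only — the ±1 mmHg
maximum permissible error of the mercury-sphygmomanometer reference;
U = K_cov·u_c with K_cov = 2 by default (renamed from K to avoid colliding
with the ensemble size).  Feature-level reports use the two-component form.
Report CSVs are rounded to 3 decimals at the CLI layer; library arithmetic
keeps full precision.

The per-subject artificial BP estimates fed to the normality summary are
generated by the same parametric construction (column means of Gaussian
draws).  Nonparametric replicate means of five values live on a small
lattice, and the Lilliefors test then rejects for discreteness (ties) rather
than non-normality — a pitfall worth noting when n is tiny.

## Evaluation protocol

Splits are always by subject; fold f tests the f-th block of
`test_subjects` subjects and trains on the next `train_subjects` cyclically,
so the test blocks partition the cohort and every subject is held out exactly
once (the last block may be smaller when sizes do not divide).  AAMI: pass
iff |ME| < 5 mmHg and SDE < 8 mmHg (n−1 divisor).  BHS: cumulative
|error| ≤ 5/10/15 mmHg percentages graded A (60/85/95), B (50/75/90),
C (40/65/85), else D, all thresholds inclusive and simultaneous; the B and C
cutoffs are the standard published protocol values.

## Problem sizes

The suite and the acceptance script run scaled-down configurations chosen as
the smallest sizes at which each property is statistically decidable: 40
subjects, B = 50, K = 5 for the end-to-end recovery; 2000 replications for
rate/coverage estimates; 10⁵ replicates per n for the frozen critical-value
table.  The full-size defaults (85 subjects, B = 100) run in seconds to
minutes on one CPU via the CLI.

## Known limitations

- The synthetic cohort's feature/pressure link is affine; real oscillometric
  features are nonlinear in the underlying pressures and the waveform
  envelope.  Recovery results here bound machinery correctness only.
- Waveform acquisition and feature extraction are out of scope; the package
  starts at the feature vector.
- The comparative benefit of boosting over a single learner is unsupported on
  synthetic data (see above).
- Small-n interval coverage is optimistic by construction (~88 % at n = 5 for
  a nominal 95 %); a t-quantile would fix it but would no longer be the
  method under study.
- The feature dimension is configurable because the named feature set (MAP,
  AR, AE, EL, MA, STD1, STD2, MAPL plus the two targets) does not fill the
  reference input width of 12; no names are invented for the remainder.
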