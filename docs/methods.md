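# Methods

## Scope and data model

The package analyses longitudinal adipose cell-size distributions: per
biopsy day, replicate histograms giving the percentage of counted cells in
each of 80 logarithmically spaced diameter bins between 20 and 240 µm.
Distributions are stored as percentages summing to 100 (raw particle counts
are normalized on input); replicates are kept as separate rows, and
day-level averaging happens only inside operations whose contract requires
it. Days are integers counted from the first biopsy. Bin "diameters" are
reported at the geometric mean of the bin edges, consistent with the
logarithmic grid; this affects labels only, never likelihoods.

The mean distribution weights days equally (replicates averaged within day
first), so days with extra replicates do not dominate; the alternative —
weighting by replicate count — changes third-decimal percentages on the
bundled schedules and none of the conclusions.

## Synthetic data generator

The raw rat histograms behind the analysis are unpublished, so the
generator stands in for them. It emulates the features the inference
relies on and is explicit about what it does not capture.

Modelled: bimodality (a lognormal small-cell mode near 35 µm with log-scale
0.22 and a large-cell mode near 100 µm with log-scale 0.30, mixed with
weight w_small); counting statistics (multinomial draws of 6,000 particles
per measurement); replicate/handling variability (independent per-bin
multiplicative lognormal noise, CV 5%, mean one); the printed irregular
schedule (16 days, 0–162, with a 14-day variant ending at 150); and a
periodic modulation of w_small with default period 56 days and amplitude
0.2 around a base of 0.5.

Two modulation modes exist because the inference model assumes the
distribution is *piecewise constant* within period-bins while biology is
smooth: `piecewise_constant` (w_small depends only on
⌊day/(T/N_b)⌋ mod N_b; matches the inference assumption exactly, so period
recovery is a well-posed test) and `smooth` (sinusoidal in the day; a
robustness stress test). Per-period-bin weights in piecewise mode sample
one sine cycle at bin midpoints.

Not modelled: secular growth of the animal (distributions are
stationary-periodic here), day-to-day drift in instrument calibration,
coincidence-counting artefacts, and any fitted resemblance to the actual
rats' histograms. Passing recovery tests therefore demonstrates that the
pipeline can detect the kind of periodicity it assumes, under realistic
counting and replicate noise — not that the biological data contained such
periodicity.

All randomness flows from one master seed through `numpy` Generators;
identical configurations reproduce byte-identical datasets.

## Model space

Enumeration covers period-bin counts 2–10 and integer bin widths 5–50 days
(both ends inclusive), phases 0..width−1, with day-to-bin assignment
⌊(day+φ)/d⌋ mod N_b — the closed form that reproduces the published
16-day assignment sequence exactly. Parameter triples inducing the same
(N_b, assignment) pair are deduplicated into one model carrying all
generating (width, phase) combos; its representative period is the midpoint
of the generating periods and its ambiguity their spread. Pruning keeps
models that are *testable* (every period-bin's occurrence positions form at
least two non-contiguous runs in the day sequence, so within-bin agreement
cannot be mere continuity) and that have at least one generating period
within the inclusive window [30, 100] days.

These conventions are pinned in `ModelSpaceConfig`, and the worked examples
in the original description (the printed assignment sequence and both
testability examples) verify them. The verbal description of the rule
leaves the deduplication convention genuinely open, and the package's
printed-count checks are sensitive to it: under the pinned rule the
enumeration yields 2366/2889 distinct models (14-/16-day schedule) before
pruning and 393/529 after, with mean period ambiguity 1.5/1.0 days and
maximum 24 days. An extensive search over alternative conventions
(inclusive/exclusive period bounds, dedup keys by assignment only, by bin
relabeling, by induced day-partition, alternative phase ranges and
real-valued widths) found none that jointly reproduces all the originally
printed statistics; the one family matching the post-pruning counts
exactly requires a width cap contradicting the stated 5–50-day range and
still misses the ambiguity statistics, so it was rejected as coincidental.
The pinned rule is the most direct reading of the stated procedure.

## Likelihood, priors and evidence

For one cell-size bin and one period-bin, observations (replicate
percentages, every replicate an independent observation in its day's
period-bin) are lognormal with that bin's (µ, σ). The full log-density is
kept including its constants so that the two marginalization routes agree
absolutely; constants cancel in model comparison anyway. Zero percentages
(possible in sparse tail bins) are floored at half of one counted particle,
100·0.5/6000 ≈ 0.00833%, configurable.

Priors are proper and uninformative: µ uniform on [log 10⁻⁴, log 200]
(log-percent scale, spanning far below half a particle and above the
100% ceiling) and σ with density ∝ 1/σ on [0.01, 5] — i.e. log-uniform.
Properness makes the evidence finite; the bounds are pinned in `PriorSpec`.
One cell-size bin (by default the highest-diameter bin) is excluded from
the evidence sum to account for the normalization constraint; the choice is
configurable and documented to change absolute evidences.

### Quadrature oracle

Per period-bin, log Z is a 2-D integral of the likelihood against the
priors. In (µ, t = log σ) coordinates the joint prior is a uniform box, so
the oracle is a plain trapezoid rule on a uniform grid, refined by doubling
(129 → … → 8193 nodes per axis) until successive estimates differ by less
than 10⁻⁴ nats. It uses only sufficient statistics (n, Σlog y, Σ(log y)²)
and was cross-checked against a semi-analytic reduction (Gaussian
µ-integral in closed form, 1-D quadrature over t) to ~10⁻⁵ nats.

### Parallel tempering with thermodynamic integration

The production route runs coupled MCMC chains at inverse temperatures β and
estimates log Z = ∫₀¹ ⟨log L⟩_β dβ by the trapezoid rule over the ladder.
Design choices that matter numerically:

- **Coordinates.** Chains move in (µ, t = log σ), where the prior is a
  uniform box: proposals need no Jacobian, support checks are box bounds,
  and the 1/σ prior cannot trap chains at small σ.
- **Ladder.** The prior admits σ = 0.01, where log-likelihoods are of order
  −10⁵; ⟨log L⟩_β therefore varies enormously near β = 0 and coarse ladders
  lose real evidence mass. The default is β = 0 plus 64 geometric points
  from 10⁻⁷ to 1. The β = 0 chain draws i.i.d. from the prior and anchors
  the integral's lower limit exactly.
- **Proposals.** Symmetric Gaussian random walks whose standard deviation
  is the step fraction times the *initial* parameter magnitude (floored at
  1.0 in log units). Freezing the scale is deliberate: a scale tied to the
  current state makes the kernel asymmetric and visibly biases the
  stationary distribution (observed as a stable ~1-nat evidence error
  before the fix). Steps grow as 1/√β so hot chains traverse the prior, and
  a 20% mixture of independence proposals drawn from the prior (valid with
  the same acceptance ratio, the prior being a uniform box) gives hot
  chains global moves into the deep low-likelihood corners.
- **Schedule.** Equilibration with temperature swaps (probability 0.05 per
  step, random adjacent pair), then all chains restart from the best
  likelihood state found and sample without further swapping, which keeps
  the integration-over-temperatures reading of the ladder valid.
- **Initialization.** Per period-bin moment matching: (µ, σ) set to the
  mean and standard deviation of the log observations, clipped into the
  prior support.

Two pinned configurations wrap these settings: `accurate_pt_config` (257
ladder points to 10⁻⁸, 64k samples, step fraction 0.3) achieves ≲0.05-nat
agreement with the quadrature oracle on small fixtures and is the
validation configuration; `fast_pt_config` (15 ladder points to 10⁻⁶,
2000/500 steps, float32 arithmetic) scores hundreds of models in tens of
seconds. The fast configuration carries a small absolute bias that is
common across models on the same data, so evidence *differences* — the
quantity model selection uses — are preserved; the recovery experiments
below confirm this empirically.

The engine is vectorized: chains for every (model, cell-size bin,
temperature) advance in lock step as numpy arrays, with models padded to a
common period-bin count (padding bins carry zero counts, contribute zero
likelihood and are never updated). Each MH step updates one period-bin's
(µ, t) pair per model, cycling through bins. Scoring a model alone versus
inside a batch reshuffles its Monte Carlo draws, so evidences can move
within Monte Carlo error; any fixed (seed, model list) is exactly
reproducible.

## Selection

Models carry a uniform prior, so posterior odds are evidence ratios. The
period posterior sums normalized model weights into half-open 5-day
intervals [30, 35) … [95, 100), each deduplicated model voting its
representative period into one interval. The no-period model (one bin,
all days pooled) is scored identically but excluded from the period
posterior; its evidence is reported as a gap against the best periodic
model.

## Recruitment oscillator

The three-compartment ODE realizes the verbal mechanism — PPAR drive
switched by the sign of L − U, recruitment proportional to P, a maturation
chain, medium→large transition proportional to L, capacity proportional to
N_m, and a maximal PPAR rise rate equal to its decay rate δ. The printed
equation bodies and parameter values of the original description are
typographically unavailable, so this realization and its defaults are the
package's own: they claim the qualitative properties (sustained periodic
recruitment with period of tens of days, period decreasing with lipid
flux, non-decreasing total cell count, θ(0) = 1) and no particular printed
period. Recruitment is taken linear in P, the simplest form consistent
with the description. Defaults: L = 1 g/day, δ = 0.2/day, r = 1, g =
0.08/day, u = 0.12 g/day per cell unit, k = 0.03 /(g·day); they produce a
44-day cycle at L = 1, lengthening to 70 days at L = 0.5.

Integration is fixed-step RK4 (default dt = 0.01 d) for cross-platform
reproducibility with a discontinuous right-hand side. With a sharp switch,
the crossing of L − U = 0 inside a step is localized by bisection on the
step fraction to 10⁻⁸ and the step split there; alternatively the switch
can be smoothed logistically with width ε·L, and periods for ε ∈ {0, 0.001,
0.01} agree within 2%. The period estimator takes the mean inter-peak
interval of the chosen variable after discarding the first quarter of the
trajectory as transient (peaks: local maxima above the post-transient
median, ≥1 day apart, at least three required); it is stable to 0.01%
under step halving at the defaults.

## Problem sizes used in the bundled studies

The recovery study runs the full 16-day schedule with 20 diameter bins,
7 true period-bins, amplitude 0.2 and the fast PT configuration over 20
seeds (~30 s per seed on one core); oracle-equivalence validation uses
fixtures of ≤8 observations per period-bin over ≥10 seeds with the accurate
configuration. The full 80-bin grid with the long-chain defaults is
supported and simply scales linearly in bins and steps.

## Known limitations

- The evidence model treats cell-size bins as independent given the
  excluded normalization bin; real histograms have smooth cross-bin
  correlations the lognormal-per-bin model ignores.
- The fast PT configuration's absolute evidences are biased by a few nats
  (common-mode); use the accurate configuration when absolute log Z
  matters.
- The enumeration's printed-count checks depend on an under-specified
  deduplication convention (see above); cross-implementation comparisons
  should compare conventions before counts.
- The generator does not model secular growth; detecting periodicity on a
  strong trend would require detrending the percentages first.
- The ODE is a schematic realization; its parameters are not calibrated to
  data, and compartment boundaries have no biophysical definition here.
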