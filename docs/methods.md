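# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `clonekinetics`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Hierarchical beta-binomial growth model

Serial variant counts for clone *c* at age *t* are modelled as

    counts ~ BetaBinomial(depth, α(t), β),  α(t) = β q(t)/(1 − q(t)),
    q(t)   = ilogit(b_total · t + u),       b_total = b_gene + b_site + b_clone.

The beta-binomial arises by compounding the binomial sequencing draw with a
Beta-distributed proportion whose mean is q(t); the parameterization via
α(t) keeps E[counts] = depth · q(t) for every β. The mutation is assumed
heterozygous and exclusive to one clone, so q is half the clone's cell
fraction and the logit-linear form is exactly the trajectory of a clone
growing at constant relative fitness in a finite population (see the
Wright–Fisher section).

Effects and priors:

* `b_gene` — one shared annual logit-scale effect per gene, prior N(0, 0.1)
  (mean, SD). Where a gene carries both truncating and missense mutations,
  the two classes get separate effects (labels `GENE:T` / `GENE:M`).
* `b_site` — one effect per *recurrent site*: a protein position with
  missense mutations in at least two individuals. A gene whose only cohort
  presence is one recurrent hotspot is modelled at the site level alone, to
  avoid a perfectly confounded gene+site pair. Prior N(0, 0.1).
* `b_clone` — per-clone "unknown-cause" residual growth, prior N(0, 0.05).
* `u` — per-clone offset at birth (age 0), prior N(−8, 50). The offset is a
  location nuisance whose true values span roughly (−45, −1) across clones:
  slow early-onset clones sit near −10, fast late-onset clones near −40. A
  tight offset prior measurably drags the growth estimates of fast clones
  downward (their likelihood constrains b·t̄ + u far more strongly than b
  alone), so we keep the prior proper but essentially flat. The recovery
  test in the acceptance suite checks the resulting interval calibration.
* `β` — overdispersion, prior N(μ_od, σ_od) from the replicate calibration,
  sampled as log β with the appropriate Jacobian; one β is shared
  cohort-wide (per-batch overdispersion is not modelled).

`vaf_ceiling` (default 1.0) rescales q(t) = ceiling · ilogit(·). The
default implements the logistic saturating at VAF 1; the biologically
motivated ceiling for a heterozygous mutation is 0.5 (a full clonal sweep
has VAF ½), and analyses that compare longitudinal with phylodynamic rates
use `vaf_ceiling=0.5` so that ilogit(b·t + u) is the clone *fraction*
itself.

### Sampling

Posteriors are drawn by Hamiltonian Monte Carlo with analytic gradients
(beta-binomial gradients via digamma functions; no autodiff dependency).
Defaults mirror the protocol the model family is usually run with: 5,000
iterations per chain with the first half discarded, 150 leapfrog steps
(jittered ±20% against periodicity), two chains. Warm-up adapts the step
size by dual averaging to an 0.8 acceptance target and estimates a diagonal
mass matrix from the middle half of warm-up. Because the likelihood
constrains b·t̄ + u (t̄ = the clone's mean observation age) much more
tightly than b or u separately, the sampler works in the exactly
reparameterized coordinates (b, v = b·t̄ + u) and converts back on output;
this removes a near-perfect posterior correlation and is what makes short
chains usable. Convergence is reported via rank-normalized split R-hat
(arviz) over all parameters; R-hat above 1.05 or any divergent transitions
raise an explicit warning with the diagnostics attached. Reduced settings
(≈ 2,000 iterations, 40–50 leapfrog steps) are used in the test suite and
acceptance script; the posterior for these smooth, low-dimensional targets
is insensitive to the cut, and the recovery tests would catch degradation.

Clones whose counts are all zero are fitted (the posterior reverts to the
prior) but listed as `uninformative`.

### Overdispersion calibration

Replicate groups (dilution series or triplicates) share one latent VAF per
group; counts are beta-binomial with β = exp(r), r unconstrained and flat,
and latent logit-VAFs given a diffuse N(−4, 3) prior. In `dilution` mode,
groups known to share a dilution level also share the latent VAF. Groups
with all-zero counts (e.g. the zero-VAF dilution) carry no information
about β and are dropped; an entirely zero replicate set is an error. The
posterior mean and SD of β over ≥ 1,000 draws become (μ_od, σ_od).

### Outlier classification

Each observation is scored by its two-sided beta-binomial tail probability,
averaged over the posterior: tail = min(P(X ≤ k), P(X ≥ k)), flagged when
below 2.5%. The beta-binomial CDF has no convenient closed form, so the
tails are computed as E_u[BinomCDF(k; n, Q_β(u))] with 48-point
Gauss–Legendre quadrature over the mixing beta's probability scale — this
matches exact summation to ~10⁻³ (tested) at a small, depth-independent
cost. A clone with no flagged observation is classified as growing at a
fixed exponential rate; the cohort proportion carries a Jeffreys
(beta-distributed) 90% interval. Under the generative model two 2.5% tails
flag ≈ 5% of observations; posterior averaging makes the test slightly
conservative when the posterior is wide, and discreteness pushes the rate
slightly below the nominal level at low depth.

## Age at onset

With q(t) = ilogit(b·t + u) and a population of n HSCs at g generations per
year, the deterministic back-extrapolation to a single-cell clone
(fraction 1/n) is t0 = (log(1/n) − u)/b. The two-phase correction first
finds when the clone entered deterministic growth, t0 + log(g/b)/b, then
subtracts the expected duration 1/b of the stochastic establishment phase:

    t0_adjusted = t0 + log(g/b)/b − 1/b.

The formula is applied for every b > 0 (at b = g the adjustment term
vanishes; onset is undefined for b ≤ 0 and raises a typed error). Defaults
n = 50,000 and g = 2 follow the standard HSC estimates; onset estimates
vary smoothly over n ∈ [10⁴, 6×10⁵] and g ∈ [1, 20] (tested).

*Minimal historical growth*: when back-extrapolation at the observed rate
lands before conception (age −1), the reported rate is the smallest b for
which a clone founded exactly at conception, with offset
u(b) = logit(q_T) − b·T pinned to the observed terminal VAF, satisfies
t0_adjusted(b) = −1. The root is found by bracketed bisection (Brent) on
(observed_b, 10] to 10⁻⁸, checked in the tests against a 10⁻⁶-step grid
search. This post-hoc solve on the fitted terminal VAF is deterministic and
testable; re-running the MCMC under an onset constraint would be the
alternative reading and is not implemented.

*Detection latency* is t_detect − t0_adjusted with
t_detect = (logit(VAF_threshold) − u)/b and threshold 0.2% by default.

Posterior propagation: the closed forms are applied to every posterior draw
of (b_total, u); draws with b ≤ 0 are dropped, and clones where most draws
are non-growing report NaN. Conception is −1 year for onset feasibility and
−0.75 year for tree time-scaling; both are configuration constants.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Wright–Fisher**: exact multinomial resampling of n cells per
  generation; a driver clone's offspring weight is (1+s) per cell. Clones
  are seeded with one cell at their onset generation (configurable
  `initial_cells` supports starting at a given fraction, e.g. for the
  neutral-martingale test). `fitness_schedule` lets s change mid-life to
  emulate deceleration. Conditional establishment (`simulate_wf_conditioned`)
  reruns until the clone survives drift, mirroring the fact that observed
  clones are survivors. Under this model logit f(t) drifts linearly at
  log(1+s) per generation while 0 ≪ f ≪ 1, which is exactly the logistic
  trajectory the longitudinal model fits; annualized, b = g·log(1+s).
* **Sequencing**: q = f/2 (heterozygous); counts beta-binomial with
  concentration β (binomial in the β → ∞ limit); q = 0 yields exact zeros.
  Cohort defaults used across the tests: visits every 5 years between ages
  55 and 75–80, depth 2,000–3,000×, β = 120 — deep targeted sequencing with
  technical noise dominating above ~1,000× depth.
* **Model-cohort sampler** (`sample_model_cohort`): draws cohorts directly
  from the hierarchical observation model (gene levels + centred per-clone
  effects with SD 0.05; offsets set so terminal VAFs are uniform in a
  plausible window, default 5–35%). Centring makes the gene effect equal
  the realized cohort mean, so gene-ordering checks test the estimator, not
  the luck of the clone draw.
* **Colony trees**: tips are assigned to clones multinomially by final
  fractions; genealogies are built backward — within-clone coalescent with
  the per-generation clone sizes from the recorded history, forced to the
  single founder cell at onset; founders and wild-type colonies then
  coalesce in the background population; lineages still distinct at birth
  coalesce during a linear 1 → n fetal expansion ending at conception
  (−0.75 y). Branch mutation counts are Poisson at 18 mutations/year
  postnatally, with 55 expected mutations spread uniformly over the
  conception→birth segment. The driver branch is the clone founder's stem.

What the generator does *not* emulate: mutation phasing ambiguity,
copy-number-altered VAFs, nested driver clones, variant-calling artefacts,
depth variation across sites, or batch structure in overdispersion. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data complications.

## Phylodynamics

* **Time calibration**: branch lengths are divided by the variant-calling
  sensitivity, the tree is made ultrametric by proportional tip-path
  normalization (each node's molecular depth is multiplied by the mean of
  target/tip-depth over the tip paths through it, then clipped monotone),
  and depth maps to time piecewise: the first 55 mutations span conception
  (−0.75 y) to birth, deeper depths scale linearly to the age at sampling.
* **Clade detection**: a clade qualifies via a driver annotation on its
  MRCA stem, or a stem longer than 10% of the tree's *time* depth with ≥ 5
  colonies (time depth, not molecular depth, is used; a switch exposes the
  choice). Nested qualifying clades report the outermost. Onset bounds are
  the two ends of the stem branch.
* **Skyline**: classic/generalized skyline on the clade's coalescent
  times — each inter-coalescent interval with k lineages and span Δt
  estimates N_eff = k(k−1)Δt/2 in HSC × years (population size times
  generation time); adjacent intervals pool until each pool spans the
  smoothing epsilon. The Gaussian-process phylodynamic machinery used in
  the literature is deliberately replaced by this transparent estimator;
  the contract (piecewise N_eff with variance flags) is the same and a
  caller can substitute an external estimator. Consequence: exact numeric
  N_eff curves from GP-based analyses are not reproduced, only their
  structure and derived ratios.
* **Variance flags**: the exponential-interval model gives
  var(N̂) = N̂²/m for a pool of m coalescences. A pooled point is flagged
  high-variance when m < 2 (relative variance above 0.5). A literal
  threshold on log(var(N_eff)) is available (`log_var_threshold`), but note
  that with var = N̂²/m any fixed threshold like 5 is crossed by *every*
  point at HSC scale (2·log N̂ ≈ 20), so that rule only makes sense in the
  internal units of the GP posterior it was originally attached to; the
  event-count rule plays the same role — marking data-poor intervals — in a
  scale-free way.
* **Biphasic fit**: continuous two-segment least squares on log N_eff with
  the breakpoint grid-searched over observed interior times (≥ 2 points per
  segment), ties to the earliest candidate; high-variance points are
  excluded. Noiseless two-segment inputs are recovered exactly when the
  true breakpoint is an observed time.
* **Deceleration**: expected size = exp(early line extrapolated to the
  sampling age); observed size = clade tip fraction × capacity (default
  200,000 HSC × yr); ratios are computed in log space. Expected growth is
  the rate of a logistic fit to the N_eff trajectory with the capacity
  fixed (scipy least squares on the log scale, initialized at the early
  rate and the observed half-capacity crossing); the growth ratio is
  late/expected — 1 means no deceleration, < 1 deceleration.

Two systematic effects matter when interpreting round-trip comparisons and
are visible in the examples: (i) conditioning on survival inflates the
apparent early growth of a clade (the drift-dominated phase of surviving
clones rises faster than (1+s) per generation), which is precisely why
extrapolating early growth overestimates observed clade sizes even at
constant fitness; (ii) once a clone occupies a sizeable fraction f of the
compartment, the slope of log N_eff is ≈ b(1−f), below the logit-scale rate
b. Rate comparisons therefore use moderately sized clades and, because a
single 96-colony tree carries large coalescent noise in its late-segment
slope, the acceptance round trip reports medians over several independent
colony samplings of the same simulated history.

## Pipeline

`run_pipeline` chains simulate → overdispersion → fit → onset →
phylodynamics → report, with per-stage toggles, per-stage seeds spawned
from one master seed (logged in the manifest), and all outputs as TSV/JSON/
YAML/Newick. Identical configuration and seed reproduce byte-identical
outputs (tested). Input validation enumerates all schema problems (column
sets, integer counts, alt ≤ depth, strictly increasing ages, parseable
Newick, non-negative branch lengths, metadata completeness) instead of
failing one at a time. The library is the primary interface; a thin typer
CLI (`clonekinetics simulate|fit|onset|phylo|run|validate`) wraps the same
functions for shell use.

## Problem sizes

Test and acceptance runs use cohorts of 36–60 clones at 5–6 timepoints,
96-colony trees, 250 established Wright–Fisher runs per selection
coefficient, 50 + 20 coalescent oracle trees, and 200 biphasic noise
replicates, with ~2,000-iteration two-chain HMC — sizes chosen so the whole
suite completes in minutes on one CPU while keeping Monte Carlo error well
inside the asserted tolerances.

## Known limitations

* One β cohort-wide; no per-batch technical structure.
* Clones are modelled independently; no phasing of co-occurring mutations
  into shared clones, no nested subclones in the generator or the trees.
* The skyline estimator is noisier than GP smoothing at small clade sizes;
  single-tree late-rate estimates should be treated as order-of-magnitude.
* The ultrametric normalization is one reasonable choice among several; it
  is isolated in one function (`scale_tree_to_time`) for replacement.
* Gene-level onset summaries beyond per-clone estimates (and simple
  medians) are reporting conveniences, not modelled quantities.
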