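# clonekinetics

Lifelong kinetics of clonal haematopoiesis: a tested Python pipeline for
modelling how blood stem-cell clones carrying somatic driver mutations grow
across the human lifespan.

Clonal haematopoiesis — the expansion of a haematopoietic stem-cell (HSC)
clone bearing a driver mutation (*DNMT3A*, *TET2*, *JAK2*, splicing genes,
…) — is near-universal in older people and shapes the risk of blood cancer.
Two complementary data types probe its dynamics: serial deep-sequencing
variant-allele fractions (VAFs), which track clones over years of follow-up
in older age, and phylogenies of single-cell-derived blood colonies, whose
branch lengths in somatic mutations reach back to conception. This package
implements the analysis stack that joins the two, exercised end to end on a
built-in Wright–Fisher/coalescent synthetic-data generator, for
population-genetics and cancer-genomics researchers who want the method
without controlled-access data.

## The models

**Longitudinal growth.** For clone *c* of individual *j*, variant read
counts at age *t* follow a hierarchical Bayesian beta-binomial logistic
model

```
counts_c(t) ~ BetaBinomial(depth, α(t), β),   α(t) = β q(t) / (1 − q(t)),
q(t) = ilogit((b_gene + b_site + b_clone) · t + u_c)
```

with gene effects shared across clones (prior N(0, 0.1)), recurrent-site
effects for hotspots mutated in ≥ 2 individuals (N(0, 0.1)), a per-clone
"unknown-cause" effect (N(0, 0.05)), a clone offset *u* at birth, and the
technical overdispersion β calibrated on replicate sequencing. Posteriors
are sampled with Hamiltonian Monte Carlo (analytic gradients, dual-averaging
step size, diagonal mass adaptation). Observations in the 2.5% tails of the
fitted beta-binomial flag non-constant growth; clones with no outliers grow
at a fixed exponential rate.

**Age at onset.** A clone fitted with growth *b* and offset *u* is
back-extrapolated to one founding cell among *n* = 50,000 HSCs at *g* = 2
generations/year through a two-phase (stochastic, then deterministic)
Wright–Fisher model:

```
t0 = (log(1/n) − u) / b,    t0_adjusted = t0 + log(g/b)/b − 1/b
```

Onsets before conception (age −1) are infeasible; the smallest rate placing
onset at conception is the clone's *minimal historical growth*.

**Phylodynamics.** Colony trees are made ultrametric and calibrated in time
(first 55 mutations span conception→birth; linear accumulation after).
Expanded clades (driver on the MRCA stem, or stem > 10% of tree depth with
≥ 5 colonies) get a coalescent skyline effective-population-size trajectory
(N_eff in HSC × years), a continuous biphasic log-linear growth fit, and
deceleration metrics: observed/expected clade size and late/expected growth
ratio at a fixed carrying capacity (200,000 HSC × yr by default).

## Worked example

Simulate a *DNMT3A* clone with a 10% per-generation advantage arising at
age 25, sequence it at five clinic visits, and fit it
(`examples/01_wright_fisher_clone.py`):

```
clone fraction by age:
  age 50: 0.0040
  age 60: 0.0259
  age 70: 0.1500
  age 75: 0.2997

sequencing table (alt_count / depth = VAF ~ clone fraction / 2):
 age_years  depth  alt_count
      55.0   3000          7
      65.0   3000        127
      75.0   3000        328

implied annual logit-scale growth b = 2 * log(1.10) = 0.191
```

Fitting a three-gene cohort (`examples/02_fit_growth_model.py`) recovers
the per-gene growth spectrum with calibrated uncertainty:

```
overdispersion beta: 135 +/- 28 (generator truth 120)
per-gene annual growth (posterior mean and 90% HPDI):
  DNMT3A: +0.046 [+0.021, +0.071] /yr     (truth 0.05)
  TET2:   +0.098 [+0.072, +0.122] /yr     (truth 0.10)
  SRSF2:  +0.138 [+0.113, +0.166] /yr     (truth 0.15)
fixed-rate clones: 94.4% (90% CI 85.5%-98.4%)
```

Onset algebra (`examples/03_onset_ages.py`): a clone with b = 0.2/yr and
u = −15 founded at 20.9 y by naive extrapolation actually started at
27.4 y once the stochastic phase is accounted for, and took 16.5 years to
become detectable at VAF 0.2%. A clone at VAF 0.2 by age 70 that now grows
at only 5%/yr must historically have grown at ≥ 0.106/yr.

Phylodynamics (`examples/04_phylodynamics.py`): a 96-colony tree from the
same simulated population yields a 24-colony driver clade whose stem
brackets the true onset, a skyline with early rate 0.33/yr and late rate
0.19/yr, and a growth ratio of 0.85 — near 1, as expected for a clone with
constant fitness (the early-rate excess is the survivorship-conditioned
stochastic phase, which is also why extrapolating early growth overshoots
the observed clade size).

`examples/05_full_pipeline.py` (or `clonekinetics run OUTDIR`) chains every
stage and writes all tables, a summary report, and a manifest that
reproduces the run from one master seed.

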