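# Methods

## The inference problem

`paleoabc` dates population splits and demographic expansions from a single
heterochronous mtDNA locus — the setting of Holarctic woolly-mammoth
phylogeography, where a few hundred radiocarbon-dated control-region
sequences (hundreds of base pairs, ages from a few kyr to ~200 kyr BP) are
partitioned into geographically structured mtDNA clades.  Likelihoods for
such structured serial-coalescent models are intractable, so inference is by
approximate Bayesian computation (ABC): simulate datasets from parameter
draws, compare summary statistics with the observed data, keep and
regression-adjust the nearest draws.

## Demographic models

Four stock scenarios cover the two headline questions (all times in calendar
years BP at the user surface; sizes are female effective sizes, appropriate
for mtDNA):

* **1A** — three demes (`europe`, `siberia`, `america`) of constant size
  `N_ef` that merge (backwards) into a single ancestral deme of size `N_anc`
  at `T_split`.  The three-way split is modelled as a simultaneous
  trichotomous merge: the analysis estimates a single split time, and a
  trichotomy is the minimal faithful reading; nested bifurcations can be
  expressed through the `custom` scenario type.
* **1B** — as 1A, plus a shared bottleneck-and-expansion: forward in time
  each deme sat at `bottleneck_frac * N_ef` until `T_growth`, then grew
  exponentially to `N_ef` at the present.  The growth rate is derived,
  `r = ln(N_ef/N_b)/T_growth`, so the trajectory is fully determined.
  `T_growth < T_split` is enforced by rejecting and redrawing invalid prior
  draws.
* **2A** — two demes (`eurasia`, `north_america`) with separate sizes,
  merging at `T_split`; no gene flow.
* **2B** — as 2A with forward-time gene flow Eurasia→North America at
  `mig_rate` per lineage per generation (backwards: lineages in North
  America jump to Eurasia), active from the present back to the split.

The three sister demes of models 1A/1B share one present-day `N_ef`: the
bottleneck and expansion are explicitly simultaneous and shared, and a
single size keeps the parameter count commensurate with a single-locus
dataset.  The ancestral size `N_anc` is a separate free parameter.

**Default priors** (uniform boxes; deliberately wide, configurable, and not
tied to any particular dataset): `N_ef`, `N_anc` and the model-2 sizes on
[100, 60 000]; `T_split` on [120, 400] kyr BP (model 1) and [20, 140] kyr BP
(model 2); `T_growth` on [60, 160] kyr BP; `mig_rate` on [0, 0.01] per
generation; `bottleneck_frac` on [0.01, 1] (a strictly positive lower bound
avoids degenerate zero-size demes).

Generation time defaults to 15 years, with 20 years as the standard
sensitivity setting; it enters only in the conversion of years to
generations and of the per-year mutation rate to a per-generation rate.

## Serial coalescent simulation

Simulation runs backwards in continuous time measured in generations, with
time 0 anchored at the youngest sample.  Tips activate at their ages;
within a deme of (piecewise-exponential) size `N(t)` each pair of active
lineages coalesces at rate `1/N(t)` (`N` is the haploid mtDNA effective
size).  Waiting times under exponential growth are drawn by analytic
inversion of the integrated hazard across size epochs — no thinning.
Migration uses constant per-lineage jump probabilities, and a merge event
transfers all lineages (and any not-yet-activated tips) of the source demes
to the destination, so samples older than the split correctly enter the
ancestral deme.  Candidate event times are cached next-reaction style: a
deme's pending coalescence draw remains valid until its lineage count
changes.  Simultaneous-event ties are resolved tips first, then
migration/coalescence, then scheduled demographic events.

Each replicate consumes one PCG64 stream seeded from `(master_seed, row)`,
making reference tables reproducible row-by-row and independent of any
batching.

## Mutation model

Finite-sites evolution on the fixed-length alignment (default L = 741 bp):
per-site relative rates are continuous i.i.d. gamma draws with shape
α = 0.107 and mean 1 (continuous rates rather than a 4-category
discretisation — the categories are an approximation artifact, not part of
the model); the mean rate is 9.56%/site/Myr, converted to a per-generation
rate with the generation time.  Each mutation is a transition with
probability 0.98 (the transition bias is an event probability on the 0–1
scale, not a κ rate ratio), otherwise one of the two transversions
uniformly.  The root sequence defaults to uniform random bases; base
composition is not modelled.  Because the process is finite-sites,
back-mutation occurs and divergence saturates below L.

Implementation: the total mutation count is Poisson with mean
`mu · Σ r_i · total branch length`; mutations are assigned sites
(∝ rate) and branches (∝ length) and states are propagated root→tips.

## Summary statistics

The standard intra/inter-population panel computed identically (same code
path) for observed and simulated data: per deme and pooled — sample size,
segregating sites S, number of haplotypes K, haplotype diversity H, mean
pairwise differences Π, per-site diversity π, Tajima's D; between demes —
Hudson-style F_ST (1 − Hw/Hb from mean pairwise differences).  `N`
characters are excluded pairwise and difference counts rescaled to L;
haplotype identity under pairwise N-deletion is resolved greedily (the
relation is not transitive; the greedy order is the documented convention).
Undefined entries (Tajima's D at S = 0 or n < 4; F_ST with Hb = 0; any
statistic at n < 2) are encoded as 0 with a mask bit; masked coordinates of
the observed vector are excluded from ABC distances for observed and
simulated vectors alike.

The model layer enables an **extended panel** by default, appending per deme
pair the mean (`dxy`), minimum (`dmin`) and smallest-decile mean (`dlow`)
between-deme pairwise differences.  The low end of the between-population
difference distribution tracks the first post-divergence coalescences and is
the classic low-variance dating signal for splits (the decile mean averages
mutational Poisson noise over pairs sharing those early coalescences), while
the mean separates divergence time from ancestral population size.  In
recovery experiments these statistics substantially tighten split-time
posteriors; the plain panel remains available (`extended_stats=False`).

## ABC engine

* **Rejection**: statistics are standardised by their median absolute
  deviation across the reference table (robust; the scaling used is not
  dictated by the genre, MAD is the package's choice).  Coordinates that are
  masked in the observed vector, constant in the table, or affine
  duplicates of an earlier coordinate (π is Π/L; duplicates would
  double-count in the distance) are dropped.  The `⌈tolerance·n⌉` draws
  nearest in Euclidean distance are kept; default tolerance 0.01.
* **Local-linear adjustment**: weighted linear regression of each parameter
  on the statistics with Epanechnikov weights over distance,
  `θ* = θ − b̂ᵀ(s − s_obs)`.  Parameters with a uniform prior are adjusted
  on a logit scale mapped from their prior box, so adjusted draws stay in
  the support.  The design is first reduced to a maximal linearly
  independent column set (pivoted QR; pooled Π is an exact combination of
  the within- and between-group means); a residual rank deficiency falls
  back to rejection with a flag.
* **Neural-network adjustment**: a single-hidden-layer tanh network
  (weighted least squares via L-BFGS, weight decay 1e-3, default 4 hidden
  units, 5 restarts) estimates the conditional expectation; adjusted draws
  are the elementwise median over restarts, on the same logit scale.  Zero
  hidden units reproduce the local-linear result exactly; non-convergence
  falls back to local-linear with a flag.  The network is implemented
  in-package because the adjustment requires Epanechnikov sample weights in
  the loss.
* **Model choice**: candidate models are compared under a common distance
  threshold on the pooled tables; posterior probabilities are acceptance
  fractions and Bayes factors their ratios (a zero count reports a bound,
  e.g. `">200"`).  A multinomial-logistic estimate (scikit-learn, trained on
  the accepted pooled draws with Epanechnikov weights) is always reported
  alongside, since count- and regression-based Bayes factors can differ.
* **Posterior summaries**: weighted medians and central 95% credibility
  intervals via linear interpolation on the weighted empirical CDF evaluated
  at each atom's mass midpoint (reduces to the usual type-7-like rule for
  equal weights).  Zero-weight draws are ignored.

## Synthetic data and recovery experiments

The generator emulates the structure of the mammoth dataset: 60 sequences
(desk scale; 320 supported) of 741 bp across the model's demes, ages
uniform per deme on 4–200 kyr BP (model family 1) or 4–60 kyr BP (family
2).  Plain uniform ages are a deliberate simplification — the radiocarbon-
limited age spectrum, clade-replacement truncations, aDNA damage and the
missing-data patterns of partial sequences are not emulated — so passing
recovery tests demonstrates correctness of the inference machinery under
the stated sampling structure, not robustness to those real-data features.

Planted truths for recovery use the headline dates (three-population split
196 kyr BP, shared expansion 121 kyr BP, two-population divergence 66 kyr
BP).  Sizes not pinned down by those headline results are fixed once:
per-deme `N_ef = 20 000` (the pre-decline female effective size scale),
`N_anc = 5 000`, `bottleneck_frac = 0.05` — a structured history carrying a
clear expansion signal.  Recovery experiments run 5×10⁴ simulations at 1%
acceptance (a desk-scale stand-in for the canonical 10⁶ iterations) and
report local-linear-adjusted posterior medians: across replicate
pseudo-datasets the network adjustment shows visibly higher
replicate-to-replicate variance at these acceptance counts, so the
local-linear estimate is the reported point estimator (both are computed
and available).

A caveat that matters for interpreting recovery scatter: with a single
non-recombining locus, the realised genealogy is one draw — between-deme
divergence carries the realised ancestral coalescence depths, so posterior
medians scatter around planted truths by roughly 10–20% across replicate
datasets even with a perfect estimator.  This is intrinsic to single-locus
dating, not Monte-Carlo error, and shrinks only with more loci.

## Numerical conventions and degenerate inputs

Ages are calendar years BP everywhere outside the simulator.  Events whose
times do not postdate the youngest sample are rejected at realization.
Structural prior constraints are handled by rejection sampling (capped at
10⁴ redraws).  Tajima's D uses the standard constants; its undefined cases
and all other undefined statistics follow the masking convention above.
F_ST never compares a sample with itself: shared-id pairs are excluded,
so a group compared against a copy of itself yields 0, and it is clipped to
[−1, 1].

## Problem sizes

Defaults are desk-scale choices that keep a full recovery experiment in the
minutes range on one core: 60-sequence datasets, 5×10⁴-row reference tables,
1% acceptance (500 accepted draws).  All sizes scale up linearly; the
full-scale canonical setting (320 sequences, 10⁶ iterations) is supported by
the same code paths.

## Known limitations

* Single-locus inference confounds split time with ancestral size along a
  ridge; the extended between-group statistics mitigate but cannot remove
  it.
* The bottleneck parameterisation (`bottleneck_frac`, derived growth rate)
  is one of several equivalent conventions; priors on it are on the
  fraction, not the rate.
* Migration is a single constant-rate interval per scenario; time-varying
  gene flow is out of scope.
* No recombination, selection, aDNA damage or sequencing error.
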