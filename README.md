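# paleoabc

Serial-coalescent simulation and approximate Bayesian computation (ABC) for
dating population splits and expansions from heterochronous mitochondrial
DNA — the kind of dataset ancient-DNA phylogeography produces: a few hundred
radiocarbon-dated control-region sequences (here 741 bp by default) spanning
the last ~200 kyr, partitioned into geographically structured mtDNA clades.
It is written for population geneticists who want a self-contained,
reproducible version of the classic "Bayesian Serial SimCoal + ABC"
workflow: demographic scenarios with uniform priors, serial coalescent
genealogies over dated tips, finite-sites mutation with gamma rate
heterogeneity and transition bias, Arlequin-style summary statistics, and
rejection ABC with local-linear and neural-network regression adjustment,
plus model choice via Bayes factors.

## The model in brief

A demographic scenario defines demes with piecewise-exponential female
effective sizes `N(t)`, merge events (population splits viewed backwards in
time), and optional gene flow.  Conditional on a parameter draw θ, a
genealogy over the dated samples is generated by the serial coalescent —
`k` active lineages in a deme coalesce at rate `k(k−1)/(2N(t))`, tips enter
the process at their calibrated ages — and sequences evolve along it under
a finite-sites model (mean rate 9.56%/site/Myr, transition probability
0.98, gamma site-rate shape α = 0.107, generation time 15 yr).  With
summary statistics `s(·)` and observed data `s_obs`, ABC keeps the draws
minimising `‖(s(θ) − s_obs)/MAD‖` (1% acceptance by default) and applies the
Beaumont local-linear correction `θ* = θ − b̂ᵀ(s − s_obs)` (or its
single-hidden-layer network analogue).  Posteriors are reported as weighted
medians with 95% credibility intervals; competing scenarios are ranked by
Bayes factors estimated from acceptance counts under a common threshold and
by multinomial logistic regression.

The four stock scenarios mirror the mammoth analyses: three clades with
constant sizes (1A) versus a shared bottleneck followed by exponential
growth (1B), and a two-population Eurasia / North America divergence without
(2A) or with (2B) subsequent gene flow.

## Worked example

Generate a pseudo-observed dataset with a planted truth (two populations
that diverged 66 kyr BP) and re-estimate the divergence time:

```python
from paleoabc import DemographicABC, build_scenario
from paleoabc.synthetic import StudyEmulationConfig, generate_pseudo_observed

cfg = StudyEmulationConfig(model_id="2A", n_samples=60, master_seed=11)
alignment, truth = generate_pseudo_observed(cfg)

model = DemographicABC(alignment, build_scenario("2A"))
result = model.fit(n_iter=20_000, tolerance=0.01, method="loclinear", seed=3)
print(result.summary())
```

```text
ABC posterior summary
==========================================================
model:            2A
samples:          60 sequences, L=741
simulations:      20000
tolerance:        0.01 (200 accepted)
adjustment:       loclinear
----------------------------------------------------------
parameter               median        2.5%       97.5%
N_eurasia                33100      9570.9       57622
N_america               4211.6        1497       10103
N_anc                   4266.2       787.9       14678
T_split                  64174       40810       96677
==========================================================
```

The planted truth was `T_split = 66 000` yr BP with `N_eurasia = 20 000`,
`N_america = 5 000` and `N_anc = 5 000`: the posterior median lands within
~3% of the true divergence time and the 95% credibility interval
comfortably brackets it.
`result.posterior` holds the adjusted draws and weights,
`result.conf_int()` the intervals, and `result.plot_posterior("T_split")` a
density figure.  Model choice works the same way through
`ModelComparisonABC(alignment, [build_scenario("2A"), build_scenario("2B")])`,
whose results expose acceptance-count and logistic-regression Bayes factors
side by side.

The same pipeline is scriptable from the shell:

```bash
paleoabc gen-data --model-id 2A --n 60 --seed 11 --out data/pseudo
paleoabc abc-fit --scenario 2A \
    --observed-fasta data/pseudo.fasta --observed-meta data/pseudo.tsv \
    --n-iter 20000 --tolerance 0.01 --method loclinear --seed 3 --out runs/fit
paleoabc model-compare --scenario 2A --scenario 2B \
    --observed-fasta data/pseudo.fasta --observed-meta data/pseudo.tsv \
    --n-iter 20000 --out runs/cmp
```

`--generation-time 20` reruns any analysis at the alternative generation
time for sensitivity checks.

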