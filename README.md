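# chronodate

Bayesian molecular-clock dating at desk scale, for phylogeneticists who want
the full machinery of modern divergence-time estimation — fossil-calibration
densities, relaxed clocks, marginal-likelihood model choice — in a
transparent, testable Python package rather than a black box.

Given a rooted binary topology with fossil calibrations and a multiple
sequence alignment, `chronodate` samples the posterior of node ages t and
branch rates r under

    p(t, r | D)  ∝  f(t) · f(r | t) · L(D | t, r),

where the time prior f(t) combines calibration densities on
fossil-constrained nodes with a birth–death kernel (λ = μ = 1, ρ = 0: the
conditional-uniform kernel) for the rest, truncated to ancestor > descendant;
f(r | t) is one of three clock models — strict (SC), independent log-normal
(IR: log r_b ~ N(log μ − σ²/2, σ²)), or autocorrelated geometric Brownian
(AR: log-rate variance σ²Δt accumulating along branches); and L is the exact
HKY+Γ pruning likelihood (or its quadratic branch-length approximation).
Clock models are compared by thermodynamic integration: the log marginal
likelihood is ∫₀¹ E_β[log L] dβ along the power-posterior path, evaluated by
Gauss–Legendre quadrature, giving Bayes factors and posterior model
probabilities. Time unit: 100 My; rates in substitutions/site/100 My.

Also included: calibration-density families B (soft-bounded uniform),
L (truncated Cauchy), ST (skew-t), S2N (skew-normal mixture), G (gamma) with
pdf/cdf/quantile/sampling and ML/moment fitting; sequential two-step dating
(posterior → skew-t calibrations → second analysis); prior-truncation
reports; infinite-sites regression; and a seeded synthetic-data generator.

## Worked example

Simulate a 4-tip strict-clock data set and re-estimate the node ages:

```python
from chronodate import *
from chronodate.time_prior import TimePriorSpec

recipe = SimulationRecipe(
    n_tips=4, root_age=0.8,
    clock=ClockModelSpec("SC", rate_prior=(2, 4)),
    subst=SubstModelSpec("JC"),
    sites_per_partition=(2000,), mu=0.3, seed=42,
)
tree, rates, aln = simulate_dataset(recipe)

ct = CalibratedTree(tree.copy(),
                    {tree.root: parse_calibration("B(0.7,0.9,0.025,0.025)")})
spec = TimePriorSpec.for_tree(ct)
like = PartitionLikelihood(aln, ct.tree, recipe.subst)
cfg = McmcConfig(iterations=8000, burnin=2000, seed=1, likelihood_mode="exact")
trace = run_mcmc(ct, spec, recipe.clock, [like], cfg)
print(summarize_trace(trace).round(4))
```

which prints

```
                mean       q2.5      q97.5        ess
parameter
t_n4          0.1652     0.1339     0.2033   936.3147
t_n5          0.2713     0.2263     0.3236   923.5869
t_n6          0.7940     0.6999     0.8989  1257.3957
mu_0          0.3034     0.2587     0.3521  1120.8311
lnL       -6571.1928 -6574.3438 -6569.7738  1252.5154
```

The true ages behind this seed are t_n4 = 0.166, t_n5 = 0.254, t_n6 = 0.8
(i.e. 16.6, 25.4 and 80 Ma) and the true rate is 0.3: every 95% CI covers
its true value, and the root posterior tracks the soft-bound calibration
B(0.7, 0.9) sharpened by the data. `t_n*` columns are node ages in 100 My;
`mu_0` is the locus mean rate; `ess` is the effective sample size.

A command-line interface mirrors the library:

```sh
chronodate simulate --recipe recipe.cfg --out data/
chronodate date --tree cal.nwk --aln aln.fa --clock ar --iter 20000 --seed 1
chronodate bf   --tree cal.nwk --aln aln.fa --clocks sc,ir,ar --bpoints 64
chronodate prior --tree cal.nwk --samples 10000
chronodate fit-calibrations --trace run.trace.tsv --nodes t_n4,t_n5 --family st
```

Calibrated trees are plain Newick with quoted internal-node labels, e.g.
`((human,chimp)'B(0.075,0.10,0.01,0.20)',gorilla);`.

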