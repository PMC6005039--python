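# Methods

`chronodate` estimates species divergence times on a fixed, rooted binary
topology by Bayesian MCMC, combining fossil-calibration densities with
molecular sequence data under relaxed molecular clocks, and selects among
clock models by thermodynamic integration. The time unit is 100 My
throughout; rates are substitutions/site/100 My. This note records the
model, the numerical choices, and what the validation experiments do and do
not demonstrate.

## Time prior

The joint prior on internal-node ages has three ingredients:

1. **Calibration densities** on fossil-constrained nodes. Five families are
   implemented (section below).
2. A **birth–death kernel** for the remaining nodes, conditioned on the root
   age. With birth = death = 1 and sampling fraction ρ = 0 — the default —
   the kernel is the uniform density on (0, t_root), so uncalibrated ages
   are conditionally i.i.d. uniform given the root. The general (λ, μ, ρ)
   kernel is implemented (λ = μ and λ ≠ μ branches, with the ρ → 0 limit
   taken analytically), but only the uniform case is exercised by the
   contract tests, because it is the only case the defaults use.
3. **Truncation**: any assignment violating ancestor > descendant has log
   prior −∞, i.e. is rejected by the sampler. The truncated density is *not*
   renormalized; the omitted constant is the same for every clock model on a
   fixed tree, so marginal-likelihood differences are unaffected.

The root must carry a calibration density or a fixed age (`FIXED(t)`),
because the kernel conditions on the root age.

A practical consequence of truncation, reproduced by
`prior_truncation_report`: a heavy-tailed (truncated-Cauchy) calibration
under the root drags the root's *marginal* prior well above the root's own
calibration density. The report prints user-density and marginal-prior
quantiles side by side so this distortion is visible before any data are
analysed.

## Calibration densities

All densities are proper on (0, ∞); parameters are validated at
construction, never at evaluation.

- **B(t_L, t_U, p_L, p_U)** — soft-bounded uniform: mass 1 − p_L − p_U is
  uniform on [t_L, t_U]; below t_L a power-law tail carries p_L, above t_U
  an exponential tail carries p_U, both matched continuously to the core
  density. When only two parameters are given, p_L = p_U = 0.025. With
  t_L = 0 the lower tail vanishes. Tail evaluation is done in log space:
  the power exponent grows like t_L/(p_L (t_U − t_L)) and overflows naive
  powers for tight bounds.
- **L(t_L, p, c, p_L)** — truncated Cauchy above a minimum: location
  t_L(1 + p), scale c·t_L, carrying 1 − p_L above t_L, with a
  continuity-matched power tail carrying p_L (default 5%) below. Defaults
  p = 0.1, c = 2. The mode sits at t_L(1 + p).
- **ST(ξ, ω, α, ν)** — skew-t (location, scale, shape, degrees of freedom).
  The pdf is analytic; the cdf is a cached monotone (PCHIP) interpolant of
  the cumulative trapezoid of the pdf on ~12000 Student-t-quantile-spaced
  abscissae, so quantiles invert the cdf to machine agreement. Sampling uses
  the scale-mixture representation (skew-normal over the square root of a
  scaled chi-square).
- **S2N(w, ξ1, ω1, α1, ξ2, ω2, α2)** — two-component skew-normal mixture
  (weight first, then two location/scale/shape triples; the printed
  seven-number form fixes this ordering).
- **G(a, b)** — gamma with shape a and rate b.

**Skew-t ML fitting** (`fit_skew_t_ml`) maximizes the log-likelihood over
(ξ, log ω, α, log ν) with L-BFGS-B, ν confined to [2.1, 10⁴] (finite
variance) and α to ±300. Because (α, ν) are weakly identified, the
optimizer restarts from a moment-based start plus four seeded jittered
starts and returns the best local optimum with a convergence flag — fits
are assessed in quantile space, not parameter space. Gamma fitting is by
moments: a = mean²/var, b = mean/var.

## Clock models

Per locus i, with mean rate μ_i and variance parameter σ²_i:

- **SC**: every branch rate equals μ_i.
- **IR**: branch log-rates i.i.d. Normal(log μ_i − σ²_i/2, σ²_i) — rate
  variance independent of timescale; the −σ²/2 term makes E[r] = μ_i.
- **AR**: geometric Brownian motion. A branch's rate is the rate at its
  child node, evolved from the parent node's rate over the branch duration
  Δt: log r ~ Normal(log r_parent − σ²Δt/2, σ²Δt), with the root rate equal
  to μ_i. Log-rate variance accumulates along paths, so rate variation grows
  with divergence time.

Across loci, (μ_1…μ_L) follow either independent gammas (`iid`) or the
gamma-Dirichlet construction (default): the locus average follows
Gamma(a, b) and the proportions a symmetric Dirichlet(α_D); the density is
obtained by exact change of variables (Jacobian L^L·mean^{L−1}). The same
construction applies to the σ²_i. α_D defaults to 1 and is configurable;
no published value exists for it. Defaults for dating runs: rate prior
G(2, 40) (nuclear scale, mean 0.05) or G(2, 8) (mixed scale, mean 0.25),
σ² prior G(1, 10); model-selection runs use G(2, 1)/G(2, 20) with σ² prior
G(1, 1).

The `iid` mode exists because the sequential two-step identity (below)
requires the per-locus priors to factorize exactly; the gamma-Dirichlet
couples loci through their average.

## Likelihood

Exact likelihoods use Felsenstein pruning over compressed site patterns
under JC or HKY with discrete-gamma rate variation (mean-of-bin
discretization, 4 categories by default). The HKY transition matrices come
from one symmetrized eigendecomposition, scaled to one expected substitution
per unit branch length. Ambiguous states (gaps, ?, N, IUPAC codes) are
fully ambiguous; a species entirely ambiguous in a partition therefore
contributes exactly nothing — numerically identical to pruning it from the
tree, which is how partition-specific taxon sets are handled.

The **approximate likelihood** for a partition is the quadratic expansion of
the branch-length log-likelihood around its maximum: b̂ by L-BFGS-B on the
exact likelihood, gradient and Hessian by central finite differences
(relative step 1e-4, with a one-shot larger-step retry when roundoff makes
the Hessian indefinite). The expansion is on untransformed branch lengths;
it is accurate within a few conditional standard errors of b̂ and
untrustworthy far away — which is exactly why power-posterior runs refuse
approximate mode (small-β chains live far from b̂). Note the classic
confound: on a rooted reversible tree only the *sum* of the two
root-adjacent branch lengths is identifiable, so the Hessian has a null
direction and marginal standard errors for those two branches are
unbounded; conditional (diagonal) curvatures remain finite.

## MCMC

Random-walk Metropolis with a fixed proposal kit: sliding window with
reflection for node ages bounded by parent/children, a boundary-anchored
multiplier for the root age, log-scale multipliers for μ_i, σ²_i and branch
rates, and a whole-tree rescale move (all sampled ages × c, all rates / c;
Jacobian c^{k−m}) that decorrelates the time/rate confound. Step sizes are
tuned every 10 sweeps during burn-in toward ~30% acceptance and frozen
afterwards. Defaults: burn-in 25% of iterations, thinning chosen to store at
most 20,000 samples, one seeded generator for the whole chain (seed recorded
in the trace header). Initialization walks the tree from a root age at the
calibration median, placing children at 75% of their parent's age (or their
calibration median when consistent); up to 100 randomized retries guard
against a zero-probability start.

Summaries are posterior means with equal-tailed 95% CIs and an effective
sample size from the initial-positive-sequence autocorrelation rule.
Between-run agreement is scored as |mean₁ − mean₂| / pooled CI width,
flagged above 0.1.

## Marginal likelihoods and model choice

log m = ∫₀¹ E_β[log L] dβ along the power-posterior path
prior × likelihood^β, evaluated by Gauss–Legendre quadrature (64 β-points by
default; configurable). One chain is run per β-point, warm-started from the
previous point's final state (prior → posterior direction), which shortens
burn-in substantially. The standard error combines per-point variances of
the mean log-likelihood, each deflated by that chain's effective sample
size. Bayes factors are reported against the best model and posterior model
probabilities assume a uniform model prior. Exactness of the quadrature is
tested on polynomials; correctness of the whole estimator on a conjugate
binomial–beta toy with an analytic marginal.

## Sequential two-step dating

If two data sets are independent given the parameters, the posterior from
the first used as the prior for the second reproduces the joint posterior —
the product rule. The implementation fits skew-t densities by ML to the
step-1 marginal posterior node ages and attaches them as calibrations for
step 2; the correlation structure of the step-1 posterior is deliberately
discarded (product of marginals), with ancestor>descendant truncation
restored by the joint time prior. Agreement with the joint analysis is
therefore approximate by design; the validation experiment requires node-age
posterior means to agree within 0.25 pooled CI widths.

## Infinite-sites diagnostics

For each node, posterior CI width w is plotted against posterior mean age t;
`infinite_sites_regression` fits w = a·t through the origin
(a = Σwt / Σt²) and reports the Pearson correlation of (t, w). In the
infinite-data limit the points fall on a line whose slope is the
fossil-driven uncertainty per unit time; curvature or scatter means sequence
data still limit precision. The correlation is reported as plain Pearson R
on (t, w); with fewer than two distinct points it is NaN with a defined
slope.

## Synthetic data

`simulate_timetree` merges random pairs of lineages at internal ages that
are sorted uniforms on (0, root age) — exactly the conditional-uniform
kernel the default time prior assumes, so simulate-then-infer experiments
are calibrated by construction. Topology law is immaterial to inference
(the topology is fixed), so uniform pair-merging is used for simplicity.
Alignments evolve site-independently (JC/HKY, optional discrete-gamma site
rates), with branch length = rate × duration per locus; an optional mask
introduces missing data. No indels are simulated, tips are extant and
contemporaneous, and alignments are error-free — so passing round-trip
tests demonstrates internal consistency of the model machinery, not
robustness to alignment error, saturation, or model misspecification in
real data.

## Validation experiment sizes

The packaged experiments (`chronodate.benchmarks`, run by
`scripts/acceptance.py`) use problem sizes chosen so the full battery runs
in minutes on one core, while keeping each check statistically meaningful:

- TI toy: K = 32 points × 10⁴ samples against the analytic value.
- Clock-model selection: 4-tip tree (ages 0.25/0.55/1.0, root soft-bounded
  at 1), HKY+Γ₄, 500 sites simulated under AR with σ² = 0.1 at the
  mitochondrial rate scale (true mean rate 1.5, rate prior G(2, 1), σ²
  prior G(1, 1)); K = 8, 3000 iterations per β-point, 5 replicates. The
  ladder tree's varied branch durations are what would let AR separate from
  IR at this size — but see the power caveat under Known limitations.
- Sequential two-step: two independent 800-site JC partitions, strict
  clock, `iid` rate priors.
- Coverage: 100 replicates × (4 tips, 1000 JC sites, strict clock, root
  fixed at truth, rate drawn from its own prior), 95% CIs vs true ages.
- Prior machinery: prior-only chains of 1.2–1.5 × 10⁵ sweeps, thinned
  before KS/quantile comparisons (KS on raw MCMC output would reject for
  autocorrelation alone).

## Known limitations

- Bayes-factor clock-model selection has limited power at desk scale: in
  the packaged 4-tip/500-site experiment with mild rate variation
  (σ² = 0.1), the free-branch-length vs strict-clock likelihood-ratio check
  does not reject the clock (p ≈ 0.24–0.99 across replicates), and the
  marginal likelihood accordingly tends to prefer the strict clock over the
  generating AR model — the parameter penalty outweighs the available
  signal. With strong rate variation (σ² = 1) the same pipeline ranks
  AR > IR > SC decisively. Reliable selection under mild variation needs
  more taxa and sites, as in genome-scale analyses.
- Fixed topology; no topology search or tip dating.
- Exact likelihood cost grows with tips and patterns; the engine is tuned
  for the few-tip regime where exact power posteriors are feasible (the
  same regime where approximate likelihood is unnecessary).
- The quadratic likelihood approximation uses no variable transform; very
  short branches sit near the boundary where its error grows fastest.
- Skew-t shape/df are reported as fitted but should be interpreted through
  the density's quantiles, not as identified parameters.
- The two root-adjacent branch lengths are individually unidentifiable in
  unrooted-likelihood terms; dating resolves this only through the prior on
  ages and rates.
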