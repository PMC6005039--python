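"""Metropolis-Hastings sampler for node ages, locus rates and sigma^2.

The target is prior(ages) x prior(rates | ages) x likelihood^beta, with
beta = 1 for ordinary dating, beta = 0 for prior-only runs and intermediate
beta for power posteriors (thermodynamic integration).  The proposal kit is
the standard one for dating MCMC: sliding windows with reflection for
bounded node ages, a boundary-anchored multiplier for the root age,
log-scale multipliers for rates and sigma^2, and a whole-tree rescale
("mixing") move that multiplies all ages by c and divides all rates by c.
Step sizes are auto-tuned toward 20-40% acceptance during burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrations import FixedAge
from .clock_models import ClockModelSpec, locus_hyperprior_logpdf
from .time_prior import TimePriorSpec, joint_time_prior_logpdf
from .treeio import CalibratedTree, Trace

__all__ = [
    "McmcConfig",
    "DatingSampler",
    "run_mcmc",
    "summarize_trace",
    "convergence_check",
    "effective_sample_size",
    "sample_scalar_target",
]


def _gamma_logpdf(x: float, a: float, b: float) -> float:
    if x <= 0:
        return -math.inf
    return a * math.log(b) + (a - 1) * math.log(x) - b * x - math.lgamma(a)


@dataclass
class McmcConfig:
    iterations: int = 10000
    burnin: int | None = None  # default: 25% of iterations
    thin: int | None = None  # default: keep at most target_samples
    seed: int | None = None
    likelihood_mode: str = "exact"  # exact | approx | none
    beta: float = 1.0
    target_samples: int = 20000
    tune: bool = True

    def __post_init__(self):
        if self.burnin is None:
            self.burnin = self.iterations // 4
        if not (self.iterations > self.burnin >= 0):
            raise ValueError("need iterations > burnin >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("power beta must be in [0, 1]")
        if self.likelihood_mode not in ("exact", "approx", "none"):
            raise ValueError("likelihood mode must be exact, approx or none")
        if self.thin is None:
            keep = self.iterations - self.burnin
            self.thin = max(1, keep // self.target_samples)


class DatingSampler:
    """One MCMC chain.  ``likelihoods`` is a per-locus list of either
    :class:`~chronodate.likelihood.PartitionLikelihood` (exact mode) or
    :class:`~chronodate.likelihood.BranchLengthApprox` (approx mode); empty
    or None for prior-only runs."""

    def __init__(
        self,
        ctree: CalibratedTree,
        time_spec: TimePriorSpec,
        clock_spec: ClockModelSpec | None,
        likelihoods,
        config: McmcConfig,
    ):
        self.ctree = ctree
        self.tree = ctree.tree
        self.time_spec = time_spec
        time_spec.require_root(ctree)
        self.clock = clock_spec
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.likelihoods = list(likelihoods or [])
        if config.likelihood_mode != "none" and not self.likelihoods:
            raise ValueError("likelihood mode requires per-locus likelihood objects")
        if config.likelihood_mode == "none":
            self.likelihoods = []
        self.n_loci = max(1, len(self.likelihoods))
        if self.clock is None and self.likelihoods:
            raise ValueError("a clock model is required when data are present")

        tree = self.tree
        self._branches = tree.branches()
        self._b_child = np.array([c for c, _ in self._branches])
        self._b_parent = np.array([p for _, p in self._branches])
        self.fixed = {
            node: d.age
            for node, d in time_spec.calibrations.items()
            if isinstance(d, FixedAge)
        }
        self.sampled_nodes = [n for n in tree.internal_nodes if n not in self.fixed]
        self._relaxed = self.clock is not None and self.clock.model in ("IR", "AR")
        root = tree.root
        self._soft_calibrated = [
            (n, d)
            for n, d in time_spec.calibrations.items()
            if not isinstance(d, FixedAge)
        ]
        self._free_nodes = np.array(
            [
                n
                for n in tree.internal_nodes
                if n != root and n not in time_spec.calibrations
            ],
            dtype=int,
        )
        from .clock_models import _branch_parent_rate_index

        self._parent_rate_idx = _branch_parent_rate_index(tree)

        self._init_state()
        self._steps: dict[str, float] = {}
        self._acc: dict[str, list[int]] = {}

    # -- state -------------------------------------------------------------
    def _init_state(self):
        tree = self.tree
        root = tree.root
        for attempt in range(100):
            ages = np.zeros(tree.n_nodes)
            if root in self.fixed:
                ages[root] = self.fixed[root]
            else:
                d = self.time_spec.calibrations[root]
                ages[root] = d.quantile(0.5) if attempt == 0 else float(d.sample(1, self.rng.integers(2**31))[0])
            # preorder fill: keep every child strictly younger than its parent
            order = [n for n in tree.postorder()[::-1] if n >= tree.n_tips and n != root]
            table = tree.children_table()
            max_tip_age = 0.0
            for node in order:
                par = int(tree.parent[node])
                if node in self.fixed:
                    ages[node] = self.fixed[node]
                    continue
                d = self.time_spec.calibrations.get(node)
                frac = 0.75 if attempt == 0 else self.rng.uniform(0.3, 0.95)
                cand = ages[par] * frac
                if d is not None:
                    med = d.quantile(0.5)
                    if 0 < med < ages[par]:
                        cand = med
                ages[node] = cand
            self.ages = ages
            if np.isfinite(self._log_time_prior()):
                break
        else:
            raise RuntimeError("could not find a valid starting configuration")

        if self.clock is not None:
            a, b = self.clock.rate_prior
            self.mu = np.full(self.n_loci, a / b)
            if self._relaxed:
                sa, sb = self.clock.sigma2_prior
                self.sigma2 = np.full(self.n_loci, sa / sb)
                self.logr = np.tile(np.log(self.mu)[:, None], (1, len(self._branches)))
            else:
                self.sigma2 = np.zeros(self.n_loci)
                self.logr = None
        else:
            self.mu = None
            self.sigma2 = None
            self.logr = None

        self._lp_time = self._log_time_prior()
        self._lp_rates = self._log_rate_prior()
        self._lnl = np.array([self._locus_lnl(i) for i in range(len(self.likelihoods))])

    def _durations(self) -> np.ndarray:
        return self.ages[self._b_parent] - self.ages[self._b_child]

    def branch_lengths(self, locus: int) -> np.ndarray:
        dt = self._durations()
        if self.clock.model == "SC":
            return self.mu[locus] * dt
        return np.exp(self.logr[locus]) * dt

    # -- target ------------------------------------------------------------
    def _log_time_prior(self) -> float:
        """Same quantity as :func:`joint_time_prior_logpdf`, evaluated on the
        sampler's arrays (hot path)."""
        ages = self.ages
        if np.any(ages[self._b_parent] <= ages[self._b_child]):
            return -math.inf
        root = self.tree.root
        t_root = float(ages[root])
        logp = 0.0
        for node, dens in self._soft_calibrated:
            val = dens.logpdf(float(ages[node]))
            if not np.isfinite(val):
                return -math.inf
            logp += float(val)
        free = ages[self._free_nodes]
        if free.size:
            if np.any(free <= 0) or np.any(free >= t_root):
                return -math.inf
            from .time_prior import _kernel_log_g

            logp += float(
                np.sum(
                    _kernel_log_g(
                        free, t_root, self.time_spec.birth, self.time_spec.death, self.time_spec.rho
                    )
                )
            )
        return logp

    def ctree_with_spec(self) -> CalibratedTree:
        # the prior reads calibrations from the spec, not the tree annotation
        return CalibratedTree(self.tree, dict(self.time_spec.calibrations))

    def _log_rate_prior(self) -> float:
        """Locus hyperprior plus branch-rate prior, inlined for the hot path
        (same quantities as :func:`locus_hyperprior_logpdf` and
        :func:`branch_rate_logprior`)."""
        if self.clock is None:
            return 0.0
        if np.any(self.mu <= 0):
            return -math.inf
        if self.n_loci == 1:
            # single locus: both hyperprior modes reduce to plain gammas
            a, b = self.clock.rate_prior
            lp = _gamma_logpdf(float(self.mu[0]), a, b)
            if self._relaxed:
                sa, sb = self.clock.sigma2_prior
                if self.sigma2[0] <= 0:
                    return -math.inf
                lp += _gamma_logpdf(float(self.sigma2[0]), sa, sb)
        else:
            lp = locus_hyperprior_logpdf(
                self.clock, self.mu, self.sigma2 if self._relaxed else None
            )
        if not np.isfinite(lp):
            return -math.inf
        if not self._relaxed:
            return lp
        logr = self.logr
        if self.clock.model == "IR":
            for i in range(self.n_loci):
                s2 = self.sigma2[i]
                mean = math.log(self.mu[i]) - s2 / 2
                dev = logr[i] - mean
                lp += float(
                    -0.5 * logr.shape[1] * math.log(2 * math.pi * s2)
                    - np.sum(dev * dev) / (2 * s2)
                    - np.sum(logr[i])
                )
            return lp
        dt = self._durations()
        if np.any(dt <= 0):
            return -math.inf
        pidx = self._parent_rate_idx
        for i in range(self.n_loci):
            var = self.sigma2[i] * dt
            parent_logr = np.where(pidx >= 0, logr[i][np.maximum(pidx, 0)], math.log(self.mu[i]))
            dev = logr[i] - (parent_logr - var / 2)
            lp += float(
                -0.5 * np.sum(np.log(2 * math.pi * var))
                - np.sum(dev * dev / (2 * var))
                - np.sum(logr[i])
            )
        return lp

    def _locus_lnl(self, locus: int) -> float:
        if not self.likelihoods:
            return 0.0
        obj = self.likelihoods[locus]
        b = self.branch_lengths(locus)
        if self.config.likelihood_mode == "exact":
            return obj.loglik(b)
        from .likelihood import approx_loglik

        return approx_loglik(obj, b)

    def log_posterior(self) -> float:
        return self._lp_time + self._lp_rates + self.config.beta * float(np.sum(self._lnl))

    # -- proposals ---------------------------------------------------------
    def _step_size(self, key: str, default: float) -> float:
        return self._steps.setdefault(key, default)

    def _record(self, key: str, accepted: bool):
        self._acc.setdefault(key, []).append(1 if accepted else 0)

    def _tune(self):
        for key, hist in self._acc.items():
            if len(hist) >= 40:
                rate = float(np.mean(hist[-40:]))
                self._steps[key] = float(
                    np.clip(self._steps[key] * math.exp(rate - 0.3), 1e-5, 1e4)
                )
                self._acc[key] = []

    def _accept(self, log_ratio: float) -> bool:
        return math.log(self.rng.uniform()) < log_ratio

    def _age_bounds(self, node: int) -> tuple[float, float]:
        lo = max(self.ages[c] for c in self.tree.children(node))
        par = self.tree.parent[node]
        hi = self.ages[par] if par >= 0 else math.inf
        return float(lo), float(hi)

    def _propose_age(self, node: int):
        lo, hi = self._age_bounds(node)
        old = self.ages[node]
        if math.isinf(hi):  # root: multiplier on the age above its oldest child
            key = "root"
            step = self._step_size(key, 0.5)
            c = math.exp(step * (self.rng.uniform() - 0.5))
            new = lo + (old - lo) * c
            log_hast = math.log(c)
        else:
            key = f"age{node}"
            width = self._step_size(key, 0.25 * (hi - lo) if hi > lo else 0.1)
            new = old + width * (self.rng.uniform() - 0.5)
            span = hi - lo
            if span <= 0:
                return
            # reflect into (lo, hi)
            y = (new - lo) % (2 * span)
            new = lo + (y if y <= span else 2 * span - y)
            log_hast = 0.0
        self.ages[node] = new
        new_lp_time = self._log_time_prior()
        new_lp_rates = self._lp_rates if not self._relaxed else self._log_rate_prior()
        new_lnl = np.array([self._locus_lnl(i) for i in range(len(self.likelihoods))])
        log_ratio = (
            (new_lp_time - self._lp_time)
            + (new_lp_rates - self._lp_rates)
            + self.config.beta * float(np.sum(new_lnl) - np.sum(self._lnl))
            + log_hast
        )
        if np.isfinite(log_ratio) and self._accept(log_ratio):
            self._lp_time, self._lp_rates, self._lnl = new_lp_time, new_lp_rates, new_lnl
            self._record(key, True)
        else:
            self.ages[node] = old
            self._record(key, False)

    def _propose_scalar(self, key: str, get, set_, loci, default_step=0.4):
        """Multiplier proposal on one positive scalar; ``loci`` lists the
        loci whose branch lengths (hence likelihoods) the scalar affects."""
        step = self._step_size(key, default_step)
        c = math.exp(step * (self.rng.uniform() - 0.5))
        old = get()
        set_(old * c)
        new_lp_rates = self._log_rate_prior()
        new_lnl = self._lnl.copy()
        for i in loci:
            if self.likelihoods:
                new_lnl[i] = self._locus_lnl(i)
        log_ratio = (
            (new_lp_rates - self._lp_rates)
            + self.config.beta * float(np.sum(new_lnl) - np.sum(self._lnl))
            + math.log(c)
        )
        if np.isfinite(log_ratio) and self._accept(log_ratio):
            self._lp_rates, self._lnl = new_lp_rates, new_lnl
            self._record(key, True)
        else:
            set_(old)
            self._record(key, False)

    def _propose_branch_rate(self, locus: int, b: int):
        key = f"r{locus}_{b}"
        step = self._step_size(key, 0.5)
        c = math.exp(step * (self.rng.uniform() - 0.5))
        old = self.logr[locus, b]
        self.logr[locus, b] = old + math.log(c)
        new_lp_rates = self._log_rate_prior()
        new_lnl = self._lnl.copy()
        if self.likelihoods:
            new_lnl[locus] = self._locus_lnl(locus)
        log_ratio = (
            (new_lp_rates - self._lp_rates)
            + self.config.beta * (float(new_lnl[locus] - self._lnl[locus]) if self.likelihoods else 0.0)
            + math.log(c)
        )
        if np.isfinite(log_ratio) and self._accept(log_ratio):
            self._lp_rates, self._lnl = new_lp_rates, new_lnl
            self._record(key, True)
        else:
            self.logr[locus, b] = old
            self._record(key, False)

    def rescale_log_accept(self, c: float) -> tuple[float, dict]:
        """Log acceptance ratio of the mixing move with factor ``c`` (all
        sampled ages x c, all rates / c), without applying it.  Returns the
        ratio and the proposed state pieces."""
        tree = self.tree
        scaled_nodes = [n for n in tree.internal_nodes if n not in self.fixed]
        old_ages = self.ages.copy()
        new_ages = self.ages.copy()
        for n in scaled_nodes:
            new_ages[n] *= c
        n_scaled = len(scaled_nodes)
        pieces = {"ages": new_ages}
        n_rates = 0
        old = (self.mu, self.logr)
        if self.clock is not None:
            pieces["mu"] = self.mu / c
            n_rates += self.n_loci
            if self._relaxed:
                pieces["logr"] = self.logr - math.log(c)
                n_rates += self.logr.size
        log_jac = (n_scaled - n_rates) * math.log(c)

        self.ages = new_ages
        if self.clock is not None:
            self.mu = pieces["mu"]
            if self._relaxed:
                self.logr = pieces["logr"]
        new_lp_time = self._log_time_prior()
        new_lp_rates = self._log_rate_prior()
        new_lnl = np.array([self._locus_lnl(i) for i in range(len(self.likelihoods))])
        log_ratio = (
            (new_lp_time - self._lp_time)
            + (new_lp_rates - self._lp_rates)
            + self.config.beta * float(np.sum(new_lnl) - np.sum(self._lnl))
            + log_jac
        )
        # restore; caller or _propose_rescale applies on acceptance
        self.ages = old_ages
        self.mu, self.logr = old
        pieces.update(lp_time=new_lp_time, lp_rates=new_lp_rates, lnl=new_lnl)
        return log_ratio, pieces

    def _propose_rescale(self):
        if self.tree.root in self.fixed:
            return
        key = "mix"
        step = self._step_size(key, 0.2)
        c = math.exp(step * (self.rng.uniform() - 0.5))
        log_ratio, pieces = self.rescale_log_accept(c)
        if np.isfinite(log_ratio) and self._accept(log_ratio):
            self.ages = pieces["ages"]
            if self.clock is not None:
                self.mu = pieces["mu"]
                if self._relaxed:
                    self.logr = pieces["logr"]
            self._lp_time = pieces["lp_time"]
            self._lp_rates = pieces["lp_rates"]
            self._lnl = pieces["lnl"]
            self._record(key, True)
        else:
            self._record(key, False)

    def sweep(self):
        for node in self.sampled_nodes:
            self._propose_age(node)
        if self.clock is not None:
            for i in range(self.n_loci):
                self._propose_scalar(
                    f"mu{i}",
                    lambda i=i: self.mu[i],
                    lambda v, i=i: self.mu.__setitem__(i, v),
                    loci=[] if self._relaxed else [i],  # under IR/AR mu moves no branch length
                )
                if self._relaxed:
                    self._propose_scalar(
                        f"s2_{i}",
                        lambda i=i: self.sigma2[i],
                        lambda v, i=i: self.sigma2.__setitem__(i, v),
                        loci=[],  # sigma2 does not move branch lengths
                    )
                    for b in range(len(self._branches)):
                        self._propose_branch_rate(i, b)
            self._propose_rescale()

    def load_state(self, other: "DatingSampler") -> None:
        """Warm-start from another sampler's current state (same model
        structure; typically the previous point on a power-posterior path)."""
        self.ages = other.ages.copy()
        if self.clock is not None and other.mu is not None:
            self.mu = other.mu.copy()
            self.sigma2 = other.sigma2.copy()
            if self._relaxed and other.logr is not None:
                self.logr = other.logr.copy()
        self._lp_time = self._log_time_prior()
        self._lp_rates = self._log_rate_prior()
        self._lnl = np.array([self._locus_lnl(i) for i in range(len(self.likelihoods))])

    # -- driver ------------------------------------------------------------
    def run(self) -> Trace:
        cfg = self.config
        rows = []
        for it in range(cfg.iterations):
            self.sweep()
            if cfg.tune and it < cfg.burnin and it % 10 == 9:
                self._tune()
            if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
                rows.append(self._snapshot(it))
        frame = pd.DataFrame(rows)
        meta = {
            "seed": cfg.seed,
            "beta": cfg.beta,
            "iterations": cfg.iterations,
            "burnin": cfg.burnin,
            "thin": cfg.thin,
            "mode": cfg.likelihood_mode,
        }
        return Trace(frame, meta)

    def _snapshot(self, it: int) -> dict:
        row = {"iter": it}
        for node in self.tree.internal_nodes:
            row[f"t_n{node}"] = float(self.ages[node])
        if self.clock is not None:
            for i in range(self.n_loci):
                row[f"mu_{i}"] = float(self.mu[i])
                if self._relaxed:
                    row[f"sigma2_{i}"] = float(self.sigma2[i])
        row["lnL"] = float(np.sum(self._lnl))
        return row


def run_mcmc(
    ctree: CalibratedTree,
    time_spec: TimePriorSpec,
    clock_spec: ClockModelSpec | None,
    likelihood,
    config: McmcConfig,
    return_sampler: bool = False,
):
    """Run one chain and return its :class:`Trace` (optionally the sampler,
    whose final state can warm-start another chain)."""
    sampler = DatingSampler(ctree, time_spec, clock_spec, likelihood, config)
    trace = sampler.run()
    if return_sampler:
        return trace, sampler
    return trace


# -- summaries --------------------------------------------------------------


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by the initial-positive-sequence rule: sum lag-pair
    autocorrelations while the pair sums stay positive."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    var = np.var(x)
    if var == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (var * n)
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    ess = n / (1 + 2 * s)
    return float(min(max(ess, 1.0), n))


def summarize_trace(trace: Trace) -> pd.DataFrame:
    """Posterior mean, equal-tailed 95% CI and ESS per parameter column."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    rows = []
    for col in trace.columns:
        if col == "iter":
            continue
        x = trace[col]
        rows.append(
            {
                "parameter": col,
                "mean": float(np.mean(x)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "ess": effective_sample_size(x),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def convergence_check(trace1: Trace, trace2: Trace, threshold: float = 0.1) -> pd.DataFrame:
    """Between-run agreement: |mean1 - mean2| / pooled 95% CI width per
    parameter, flagged when above ``threshold``."""
    if set(trace1.columns) != set(trace2.columns):
        raise ValueError("traces have different columns")
    s1, s2 = summarize_trace(trace1), summarize_trace(trace2)
    rows = []
    for par in s1.index:
        w1 = s1.loc[par, "q97.5"] - s1.loc[par, "q2.5"]
        w2 = s2.loc[par, "q97.5"] - s2.loc[par, "q2.5"]
        pooled = (w1 + w2) / 2
        diff = abs(s1.loc[par, "mean"] - s2.loc[par, "mean"])
        score = 0.0 if pooled == 0 and diff == 0 else diff / pooled if pooled > 0 else math.inf
        rows.append({"parameter": par, "score": score, "flagged": score > threshold})
    return pd.DataFrame(rows).set_index("parameter")


def sample_scalar_target(logpdf, x0: float, n: int, seed=None, step: float = 1.0,
                         burnin: int | None = None, lower: float = -math.inf,
                         upper: float = math.inf) -> np.ndarray:
    """Plain 1-D random-walk Metropolis; used for smoke tests and toy
    thermodynamic-integration targets."""
    rng = np.random.default_rng(seed)
    if burnin is None:
        burnin = n // 5
    x = float(x0)
    lp = logpdf(x)
    out = np.empty(n)
    total = n + burnin
    for i in range(total):
        y = x + step * (rng.uniform() - 0.5)
        if lower < y < upper:
            lpy = logpdf(y)
            if math.log(rng.uniform()) < lpy - lp:
                x, lp = y, lpy
        if i >= burnin:
            out[i - burnin] = x
    return out
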