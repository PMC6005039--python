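"""Priors and simulators for branch substitution rates.

Three clock models, with rates in substitutions/site/100 My:

SC  strict clock: every branch of locus i evolves at the locus mean rate mu_i.
IR  independent log-normal rates: log r_b ~ Normal(log mu_i - sigma_i^2/2,
    sigma_i^2) i.i.d. across branches; rate-variance does not depend on the
    timescale.
AR  autocorrelated (geometric Brownian) rates: each node inherits its
    parent's rate and drifts, log r ~ Normal(log r_parent - sigma_i^2 dt / 2,
    sigma_i^2 dt) over the elapsed time dt, starting from mu_i at the root;
    log-rate variance grows with divergence time.  Both the IR and AR
    corrections of -variance/2 keep E[r] equal to the parent rate (AR) or
    mu_i (IR).

Across loci, the locus means mu_i (and the sigma_i^2) follow either
independent gamma priors or a gamma-Dirichlet: the average over loci follows
Gamma(a, b) and the proportions follow a symmetric Dirichlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats, special

from .treeio import TimeTree

__all__ = [
    "ClockModelSpec",
    "LocusRates",
    "branch_rate_logprior",
    "locus_hyperprior_logpdf",
    "simulate_branch_rates",
]

_MODELS = ("SC", "IR", "AR")


@dataclass
class ClockModelSpec:
    model: str = "SC"
    rate_prior: tuple[float, float] = (2.0, 40.0)  # Gamma(shape, rate) on mean rate
    sigma2_prior: tuple[float, float] | None = (1.0, 10.0)
    dirichlet_alpha: float = 1.0
    hyperprior_mode: str = "gamma_dirichlet"  # or "iid"

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"clock model must be one of {_MODELS}")
        if min(self.rate_prior) <= 0:
            raise ValueError("rate prior hyperparameters must be positive")
        if self.model == "SC":
            self.sigma2_prior = None
        elif self.sigma2_prior is None or min(self.sigma2_prior) <= 0:
            raise ValueError("IR/AR need a positive sigma2 prior")
        if self.dirichlet_alpha <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.hyperprior_mode not in ("gamma_dirichlet", "iid"):
            raise ValueError("hyperprior_mode must be 'gamma_dirichlet' or 'iid'")


@dataclass
class LocusRates:
    """Per-locus mean rates, sigma^2 and per-branch rates.

    ``branch_rates`` has shape (L, n_branches) with branches ordered as
    ``TimeTree.branches()`` (a branch is named by its child node).
    """

    mu: np.ndarray
    sigma2: np.ndarray
    branch_rates: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.branch_rates = np.atleast_2d(np.asarray(self.branch_rates, dtype=float))
        if np.any(self.mu <= 0) or np.any(self.sigma2 < 0) or np.any(self.branch_rates <= 0):
            raise ValueError("rates must be positive")


def _branch_parent_rate_index(tree: TimeTree) -> np.ndarray:
    """For each branch (ordered by child node), the branch index whose rate
    is the parent-node rate, or -1 when the parent is the root."""
    branches = tree.branches()
    pos = {child: k for k, (child, _) in enumerate(branches)}
    out = np.empty(len(branches), dtype=int)
    for k, (_, par) in enumerate(branches):
        out[k] = pos.get(par, -1)
    return out


def branch_rate_logprior(spec: ClockModelSpec, tree: TimeTree, rates: LocusRates) -> float:
    """Log density of the branch rates given the locus means and sigma^2."""
    if np.any(rates.branch_rates <= 0):
        raise ValueError("branch rates must be positive")
    if spec.model == "SC":
        if not np.allclose(rates.branch_rates, rates.mu[:, None]):
            raise ValueError("under SC all branch rates must equal the locus mean")
        return 0.0
    logp = 0.0
    logr = np.log(rates.branch_rates)
    if spec.model == "IR":
        for i in range(len(rates.mu)):
            s2 = rates.sigma2[i]
            mean = math.log(rates.mu[i]) - s2 / 2
            logp += float(
                np.sum(stats.norm.logpdf(logr[i], loc=mean, scale=math.sqrt(s2)))
                - np.sum(logr[i])
            )
        return logp
    # AR: geometric Brownian motion along branches, root rate = mu_i
    durations = tree.branch_durations()
    parent_idx = _branch_parent_rate_index(tree)
    for i in range(len(rates.mu)):
        s2 = rates.sigma2[i]
        parent_logr = np.where(
            parent_idx >= 0, logr[i][np.maximum(parent_idx, 0)], math.log(rates.mu[i])
        )
        var = s2 * durations
        mean = parent_logr - var / 2
        logp += float(
            np.sum(stats.norm.logpdf(logr[i], loc=mean, scale=np.sqrt(var))) - np.sum(logr[i])
        )
    return logp


def _gamma_dirichlet_logpdf(x: np.ndarray, a: float, b: float, alpha: float) -> float:
    """Log density of a positive vector whose mean follows Gamma(a, b) and
    whose proportions x_i / (L xbar) follow a symmetric Dirichlet(alpha)."""
    L = x.size
    xbar = float(np.mean(x))
    logp = float(stats.gamma.logpdf(xbar, a, scale=1.0 / b))
    if L == 1:
        return logp
    props = x / (L * xbar)
    logp += float(
        special.gammaln(L * alpha)
        - L * special.gammaln(alpha)
        + (alpha - 1) * np.sum(np.log(props))
    )
    # Jacobian of (xbar, proportions) -> x is L^L * xbar^(L-1)
    logp -= L * math.log(L) + (L - 1) * math.log(xbar)
    return logp


def locus_hyperprior_logpdf(spec: ClockModelSpec, mu, sigma2=None) -> float:
    """Log prior of the locus mean rates (and sigma^2 for IR/AR)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu <= 0):
        return -math.inf
    a, b = spec.rate_prior
    if spec.hyperprior_mode == "iid":
        logp = float(np.sum(stats.gamma.logpdf(mu, a, scale=1.0 / b)))
    else:
        logp = _gamma_dirichlet_logpdf(mu, a, b, spec.dirichlet_alpha)
    if spec.model == "SC":
        return logp
    if sigma2 is None:
        raise ValueError("IR/AR require sigma2")
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    if sigma2.size != mu.size:
        raise ValueError("mu and sigma2 must have the same length")
    if np.any(sigma2 <= 0):
        return -math.inf
    sa, sb = spec.sigma2_prior
    if spec.hyperprior_mode == "iid":
        logp += float(np.sum(stats.gamma.logpdf(sigma2, sa, scale=1.0 / sb)))
    else:
        logp += _gamma_dirichlet_logpdf(sigma2, sa, sb, spec.dirichlet_alpha)
    return logp


def simulate_branch_rates(
    spec: ClockModelSpec,
    tree: TimeTree,
    n_loci: int = 1,
    seed=None,
    mu=None,
    sigma2=None,
) -> LocusRates:
    """Draw locus hyperparameters (unless fixed) and branch rates.

    The simulator is the exact twin of :func:`branch_rate_logprior`.
    """
    rng = np.random.default_rng(seed)
    a, b = spec.rate_prior
    if mu is None:
        if spec.hyperprior_mode == "iid":
            mu = rng.gamma(a, 1.0 / b, size=n_loci)
        else:
            mean = rng.gamma(a, 1.0 / b)
            props = rng.dirichlet([spec.dirichlet_alpha] * n_loci)
            mu = n_loci * mean * props
    mu = np.broadcast_to(np.atleast_1d(np.asarray(mu, dtype=float)), (n_loci,)).copy()
    if spec.model == "SC":
        sigma2 = np.zeros(n_loci)
    elif sigma2 is None:
        sa, sb = spec.sigma2_prior
        if spec.hyperprior_mode == "iid":
            sigma2 = rng.gamma(sa, 1.0 / sb, size=n_loci)
        else:
            mean = rng.gamma(sa, 1.0 / sb)
            props = rng.dirichlet([spec.dirichlet_alpha] * n_loci)
            sigma2 = n_loci * mean * props
    sigma2 = np.broadcast_to(np.atleast_1d(np.asarray(sigma2, dtype=float)), (n_loci,)).copy()

    branches = tree.branches()
    nb = len(branches)
    rates = np.empty((n_loci, nb))
    if spec.model == "SC":
        rates[:] = mu[:, None]
    elif spec.model == "IR":
        for i in range(n_loci):
            s2 = sigma2[i]
            rates[i] = np.exp(
                rng.normal(math.log(mu[i]) - s2 / 2, math.sqrt(s2), size=nb)
            )
    else:  # AR: walk root -> tips so parents are drawn before children
        durations = tree.branch_durations()
        parent_idx = _branch_parent_rate_index(tree)
        order = sorted(range(nb), key=lambda k: -tree.ages[branches[k][1]])
        for i in range(n_loci):
            s2 = sigma2[i]
            logr = np.empty(nb)
            for k in order:
                parent_logr = math.log(mu[i]) if parent_idx[k] < 0 else logr[parent_idx[k]]
                var = s2 * durations[k]
                logr[k] = rng.normal(parent_logr - var / 2, math.sqrt(var))
            rates[i] = np.exp(logr)
    return LocusRates(mu, sigma2, rates)
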