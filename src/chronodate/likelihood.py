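"""Sequence likelihoods on a rooted tree.

Exact per-partition likelihood under JC or HKY with discrete-gamma
among-site rate variation (Felsenstein pruning over compressed site
patterns), and the quadratic approximation to the branch-length
log-likelihood (value, gradient and Hessian at the maximum) used to speed up
dating MCMC.  Branch lengths are expected substitutions per site, ordered as
``TimeTree.branches()``; clock models supply length = rate x duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .treeio import Alignment, TimeTree

__all__ = [
    "SubstModelSpec",
    "PartitionLikelihood",
    "exact_loglik",
    "BranchLengthApprox",
    "build_branch_approx",
    "approx_loglik",
    "discrete_gamma_rates",
]


@dataclass
class SubstModelSpec:
    model: str = "JC"
    kappa: float = 2.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None  # None: no among-site rate variation
    ncat: int = 4

    def __post_init__(self):
        if self.model not in ("JC", "HKY"):
            raise ValueError("substitution model must be JC or HKY")
        if self.model == "JC":
            self.kappa = 1.0
            self.pi = (0.25, 0.25, 0.25, 0.25)
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("base frequencies must be 4 positive numbers summing to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.ncat < 1:
            raise ValueError("need at least one rate category")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_categories(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.ncat)


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean-of-bin discretization of Gamma(shape, shape) into equal-mass
    categories (mean rate 1)."""
    if ncat == 1:
        return np.ones(1)
    qs = np.arange(1, ncat) / ncat
    # bin boundaries on the Gamma(shape, rate=shape) scale
    bounds = special.gammaincinv(shape, qs) / shape
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # mean of Gamma(a, a) within [lo, hi] x ncat: uses the Gamma(a+1) cdf
    upper = special.gammainc(shape + 1, shape * edges[1:])
    lower = special.gammainc(shape + 1, shape * edges[:-1])
    return (upper - lower) * ncat


def _hky_eigen(kappa: float, pi: np.ndarray):
    """Eigendecomposition of the reversible HKY rate matrix scaled to one
    expected substitution per unit branch length."""
    q = np.empty((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = kappa * pi[j] if (i, j) in transitions else pi[j]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(q)))
    q /= scale
    d = np.sqrt(pi)
    sym = (q * d[:, None]) / d[None, :]
    lam, vec = np.linalg.eigh((sym + sym.T) / 2)
    u = vec / d[:, None]
    uinv = vec.T * d[None, :]
    return lam, u, uinv


class PartitionLikelihood:
    """Pruning likelihood for one alignment partition on a fixed topology.

    Site patterns are compressed once at construction; fully ambiguous rows
    (species absent from the partition) contribute nothing, exactly as if
    they had been pruned from the tree.
    """

    def __init__(self, aln: Alignment, tree: TimeTree, model: SubstModelSpec, partition: int = 0):
        missing = set(tree.tip_names) - set(aln.names)
        if missing:
            raise ValueError(f"tips absent from alignment: {sorted(missing)}")
        sub = aln.partition(partition)
        rows = [aln.names.index(nm) for nm in tree.tip_names]
        data = sub[rows]
        if data.shape[1] == 0:
            raise ValueError("partition has no sites")
        patterns, counts = np.unique(data.T, axis=0, return_counts=True)
        self.tree = tree
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.model = model
        self.rates = model.rate_categories()
        self.pi = np.asarray(model.pi, dtype=float)
        self._lam, self._u, self._uinv = _hky_eigen(model.kappa, self.pi)
        self._ut = np.ascontiguousarray(self._u.T)
        self._uinv_t = np.ascontiguousarray(self._uinv.T)
        # tip conditional likelihoods, shape (n_tips, P, 4)
        n_tips = tree.n_tips
        tipL = np.zeros((n_tips, self.n_patterns, 4))
        for i in range(n_tips):
            codes = patterns[:, i]
            amb = codes < 0
            tipL[i, amb, :] = 1.0
            tipL[i, ~amb, codes[~amb]] = 1.0
        self._tipL = tipL
        branches = tree.branches()
        self._branch_of = {child: k for k, (child, _) in enumerate(branches)}
        self._post_internal = [n for n in tree.postorder() if n >= tree.n_tips]
        self._children = tree.children_table()
        # flattened (node, [(child, branch_index), ...]) schedule for the hot loop
        self._schedule = [
            (node, [(c, self._branch_of[c]) for c in self._children[node]])
            for node in self._post_internal
        ]
        self.n_branches = len(branches)
        self.n_var_sites = int(
            sum(c for p, c in zip(patterns, counts) if len({s for s in p if s >= 0}) > 1)
        )

    def loglik(self, blens: np.ndarray) -> float:
        """Log-likelihood at the given branch lengths (>= 0 elementwise)."""
        blens = np.asarray(blens, dtype=float)
        if blens.shape != (self.n_branches,):
            raise ValueError(f"expected {self.n_branches} branch lengths")
        if np.any(blens < 0):
            return -math.inf
        # transition matrices P(b*r) = U diag(exp(lam*b*r)) U^-1, transposed
        # once so messages are plain batched matmuls lc @ P^T
        expo = np.exp(np.multiply.outer(np.multiply.outer(blens, self.rates), self._lam))
        pmat_t = np.matmul(self._uinv_t, expo[..., None] * self._ut)
        np.clip(pmat_t, 0.0, None, out=pmat_t)

        partial: dict[int, np.ndarray] = {}
        logscale = 0.0
        n_tips = self.tree.n_tips
        for node, kids in self._schedule:
            acc = None
            for child, b in kids:
                lc = self._tipL[child] if child < n_tips else partial.pop(child)
                msg = np.matmul(lc, pmat_t[b])
                acc = msg if acc is None else acc * msg
            top = acc.max()
            if top <= 0:
                return -math.inf
            if top < 1e-200 or top > 1e200:
                acc = acc / top
                logscale += math.log(top) * float(self.counts.sum())
            partial[node] = acc
        root = partial[self.tree.root]
        site = (root @ self.pi).mean(axis=0)
        if np.any(site <= 0):
            return -math.inf
        return float(np.dot(self.counts, np.log(site))) + logscale


def exact_loglik(
    aln: Alignment,
    tree: TimeTree,
    blens,
    model: SubstModelSpec,
    partition: int = 0,
) -> float:
    """One-shot exact log-likelihood; for repeated evaluation build a
    :class:`PartitionLikelihood` once and call ``loglik``."""
    return PartitionLikelihood(aln, tree, model, partition).loglik(np.asarray(blens, float))


# -- quadratic approximation ------------------------------------------------


@dataclass
class BranchLengthApprox:
    """Taylor expansion of a partition's branch-length log-likelihood around
    its maximum: value, gradient and (symmetric) Hessian at ``b_hat``."""

    b_hat: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray
    loglik_at_max: float
    converged: bool = True
    has_variable_sites: bool = True

    def __post_init__(self):
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        nb = self.b_hat.size
        if self.gradient.shape != (nb,) or self.hessian.shape != (nb, nb):
            raise ValueError("gradient/Hessian dimensions do not match b_hat")

    def standard_errors(self) -> np.ndarray:
        cov = np.linalg.pinv(-self.hessian)
        return np.sqrt(np.clip(np.diag(cov), 0, None))


def build_branch_approx(
    aln: Alignment,
    tree: TimeTree,
    model: SubstModelSpec,
    partition: int = 0,
    start: np.ndarray | None = None,
) -> BranchLengthApprox:
    """Maximize the exact likelihood over branch lengths and expand around
    the optimum (central finite differences, relative step 1e-4)."""
    pl = PartitionLikelihood(aln, tree, model, partition)
    nb = pl.n_branches
    if start is None:
        # clock-scaled start: grid-search one overall rate on the tree's
        # durations, robust even near saturation
        dur = np.maximum(tree.branch_durations(), 1e-6)
        grid = np.geomspace(1e-3, 20.0, 40)
        best_m = grid[int(np.argmax([pl.loglik(m * dur) for m in grid]))]
        x0 = best_m * dur
    else:
        x0 = np.asarray(start, dtype=float)

    def neg(b):
        val = -pl.loglik(np.maximum(b, 0.0))
        return val if np.isfinite(val) else 1e10

    res = optimize.minimize(
        neg, np.clip(x0, 1e-6, 50.0), method="L-BFGS-B", bounds=[(0.0, 50.0)] * nb,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    b_hat = np.maximum(res.x, 1e-8)
    ll0 = -float(res.fun)
    grad, hess = _fd_grad_hess(pl.loglik, b_hat)
    hess = (hess + hess.T) / 2
    # a maximum must have a negative-semidefinite Hessian; retry with a
    # larger step (Richardson-style fallback) if roundoff says otherwise
    if np.max(np.linalg.eigvalsh(hess)) > 1e-6:
        grad2, hess2 = _fd_grad_hess(pl.loglik, b_hat, rel_step=1e-3)
        hess2 = (hess2 + hess2.T) / 2
        if np.max(np.linalg.eigvalsh(hess2)) < np.max(np.linalg.eigvalsh(hess)):
            grad, hess = grad2, hess2
    return BranchLengthApprox(
        b_hat, grad, hess, ll0,
        converged=bool(res.success),
        has_variable_sites=pl.n_var_sites > 0,
    )


def _fd_grad_hess(fun, x: np.ndarray, rel_step: float = 1e-4):
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    grad = np.empty(n)
    hess = np.empty((n, n))
    f0 = fun(x)
    fplus = np.empty(n)
    fminus = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fplus[i] = fun(x + e)
        fminus[i] = fun(np.maximum(x - e, 0.0))
        grad[i] = (fplus[i] - fminus[i]) / (2 * h[i])
        hess[i, i] = (fplus[i] - 2 * f0 + fminus[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            e = np.zeros(n)
            e[i], e[j] = h[i], h[j]
            fpp = fun(x + e)
            e2 = np.zeros(n)
            e2[i], e2[j] = h[i], -h[j]
            fpm = fun(np.maximum(x + e2, 0.0))
            fmp = fun(np.maximum(x - e2, 0.0))
            fmm = fun(np.maximum(x - e, 0.0))
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return grad, hess


def approx_loglik(approx: BranchLengthApprox, blens) -> float:
    """Quadratic approximation at the proposed branch lengths.

    Accurate near ``b_hat``; far from the optimum it may diverge from the
    exact likelihood (it stays finite, but should not be trusted there).
    """
    b = np.asarray(blens, dtype=float)
    if b.shape != approx.b_hat.shape:
        raise ValueError("branch length vector has wrong dimension")
    d = b - approx.b_hat
    return float(
        approx.loglik_at_max + approx.gradient @ d + 0.5 * d @ approx.hessian @ d
    )
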