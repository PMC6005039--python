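"""Joint prior on node ages.

Calibrated nodes carry their fossil calibration densities; the remaining
internal nodes are filled in with a birth-death kernel conditioned on the
root age; truncation (every ancestor strictly older than its descendants) is
enforced implicitly by a -inf log prior, i.e. rejection inside the MCMC, with
no renormalization.  With birth rate = death rate = 1 and sampling fraction
rho = 0 the kernel is the uniform density on (0, root age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibrations import CalibrationDensity, FixedAge
from .treeio import CalibratedTree

__all__ = ["TimePriorSpec", "bd_kernel_logdensity", "joint_time_prior_logpdf", "sample_time_prior"]


@dataclass
class TimePriorSpec:
    """Birth-death kernel parameters plus per-node calibrations.

    Defaults (birth = death = 1, rho = 0) give the conditional-uniform
    kernel.  The root must be calibrated or fixed, because the kernel
    conditions on the root age.
    """

    birth: float = 1.0
    death: float = 1.0
    rho: float = 0.0
    calibrations: dict[int, CalibrationDensity] = field(default_factory=dict)

    def __post_init__(self):
        if self.birth < 0 or self.death < 0:
            raise ValueError("birth and death rates must be non-negative")
        if not 0 <= self.rho <= 1:
            raise ValueError("sampling fraction must be in [0,1]")

    @classmethod
    def for_tree(cls, ctree: CalibratedTree, birth=1.0, death=1.0, rho=0.0) -> "TimePriorSpec":
        spec = cls(birth, death, rho, dict(ctree.calibrations))
        spec.require_root(ctree)
        return spec

    def require_root(self, ctree: CalibratedTree) -> None:
        root = ctree.tree.root
        if root not in self.calibrations:
            raise ValueError("the root must carry a calibration density or fixed age")

    def fixed_nodes(self) -> dict[int, float]:
        return {
            node: d.age for node, d in self.calibrations.items() if isinstance(d, FixedAge)
        }


def _kernel_log_g(t: np.ndarray, t_root: float, lam: float, mu: float, rho: float) -> np.ndarray:
    """Per-node log kernel density g(t | t_root) on (0, t_root).

    lam = mu, rho = 0   : uniform, g = 1/t_root.
    lam = mu, rho > 0   : g(t) = (1 + rho*lam*t_root) / (t_root * (1 + rho*lam*t)^2).
    lam != mu           : for rho = 0, the limiting form g(t) proportional to
                          exp((lam-mu) t); for rho > 0 the full expression.
    """
    t = np.asarray(t, dtype=float)
    if lam == mu:
        if rho == 0.0:
            return np.full_like(t, -math.log(t_root))
        a = rho * lam
        return (
            math.log1p(a * t_root) - math.log(t_root) - 2 * np.log1p(a * t)
        )
    d = lam - mu
    if rho == 0.0:
        # exp(d t) on (0, t_root), normalized
        return d * t + math.log(abs(d)) - math.log(abs(math.expm1(d * t_root)))

    def p0(s):  # probability a lineage at time s leaves no sampled descendant's complement
        return rho * d / (rho * lam + (lam * (1 - rho) - mu) * np.exp(-d * s))

    v = 1 - p0(t_root) * math.exp(-d * t_root) / rho
    g = lam * p0(t) ** 2 * np.exp(-d * t) / (rho * v)
    return np.log(g)


def bd_kernel_logdensity(
    spec: TimePriorSpec, ages: np.ndarray, t_root: float
) -> float:
    """Sum of log kernel densities for the given non-root, uncalibrated ages,
    conditioned on the root age.  Ages at or beyond the root return -inf."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return 0.0
    if np.any(ages <= 0) or np.any(ages >= t_root):
        return -math.inf
    return float(np.sum(_kernel_log_g(ages, t_root, spec.birth, spec.death, spec.rho)))


def joint_time_prior_logpdf(
    ctree: CalibratedTree, spec: TimePriorSpec, ages: dict[int, float] | np.ndarray
) -> float:
    """Log joint prior of a complete internal-node age assignment.

    The sum of log calibration densities over calibrated nodes plus the
    birth-death kernel over uncalibrated (non-root) nodes; -inf whenever any
    parent is not strictly older than a child.  The normalizing constant of
    the truncation is omitted (sufficient for MCMC and consistent across
    clock models on a fixed tree).
    """
    tree = ctree.tree
    if isinstance(ages, dict):
        age_map = dict(ages)
    else:
        ages = np.asarray(ages, dtype=float)
        age_map = {node: float(ages[k]) for k, node in enumerate(tree.internal_nodes)}
    for node in tree.internal_nodes:
        if node not in age_map:
            raise ValueError(f"internal node {node} missing an age")
    full = np.zeros(tree.n_nodes)
    for node, t in age_map.items():
        full[node] = t
    # truncation: every ancestor strictly older
    for child, par in tree.branches():
        if full[par] <= full[child]:
            return -math.inf
    if any(t <= 0 for node, t in age_map.items()):
        return -math.inf

    root = tree.root
    t_root = full[root]
    logp = 0.0
    free_ages = []
    for node in tree.internal_nodes:
        d = spec.calibrations.get(node)
        if d is None:
            if node != root:
                free_ages.append(full[node])
            continue
        if isinstance(d, FixedAge):
            if not math.isclose(full[node], d.age, rel_tol=0, abs_tol=1e-12):
                return -math.inf
            continue
        val = d.logpdf(full[node])
        if not np.isfinite(val):
            return -math.inf
        logp += float(val)
    logp += bd_kernel_logdensity(spec, np.array(free_ages), t_root)
    return logp


def sample_time_prior(ctree: CalibratedTree, spec: TimePriorSpec, n: int, seed=None, **kwargs):
    """MCMC sample from the joint time prior (no sequence data).

    Thin wrapper over the sampler with likelihood mode ``none``; returns a
    :class:`~chronodate.treeio.Trace` whose ``t_*`` columns are the marginal
    priors of node ages.
    """
    from .mcmc import McmcConfig, run_mcmc

    config = McmcConfig(
        iterations=kwargs.pop("iterations", max(2 * n, 1000)),
        burnin=kwargs.pop("burnin", None),
        thin=kwargs.pop("thin", None),
        seed=seed,
        likelihood_mode="none",
        target_samples=n,
    )
    return run_mcmc(ctree, spec, clock_spec=None, likelihood=None, config=config)
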