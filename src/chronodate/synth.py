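"""Seed-reproducible synthetic data with the structure the inference assumes.

Time-trees are drawn by merging random pairs of lineages at internal ages
that are sorted uniforms on (0, root age) - the conditional-uniform kernel
the time prior assumes - so simulate-then-infer round trips are exactly
calibrated.  Alignments are evolved site-independently under JC/HKY with
optional discrete-gamma rate mixing, with branch length = rate x duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clock_models import ClockModelSpec, LocusRates, simulate_branch_rates
from .likelihood import SubstModelSpec, _hky_eigen
from .treeio import Alignment, TimeTree

__all__ = ["SimulationRecipe", "simulate_timetree", "simulate_alignment", "simulate_dataset"]


@dataclass
class SimulationRecipe:
    n_tips: int = 4
    root_age: float = 1.0
    clock: ClockModelSpec = field(default_factory=ClockModelSpec)
    subst: SubstModelSpec = field(default_factory=SubstModelSpec)
    sites_per_partition: tuple[int, ...] = (1000,)
    mu: float | None = None  # fixed true locus mean rate(s); None: draw from prior
    sigma2: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2 or self.root_age <= 0:
            raise ValueError("need >= 2 tips and positive root age")
        if any(s < 1 for s in self.sites_per_partition):
            raise ValueError("site counts must be >= 1")


def simulate_timetree(n_tips: int, root_age: float = 1.0, seed=None,
                      tip_names: list[str] | None = None) -> TimeTree:
    """Random labelled topology with internal ages that are sorted uniforms
    on (0, root_age); merging lineages youngest-first keeps every parent
    strictly older than its children."""
    rng = np.random.default_rng(seed)
    if tip_names is None:
        tip_names = [f"T{i+1}" for i in range(n_tips)]
    if len(tip_names) != n_tips:
        raise ValueError("tip_names length must equal n_tips")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    ages = np.zeros(n_nodes)
    if n_tips == 2:
        inner = np.array([])
    else:
        inner = np.sort(rng.uniform(0, root_age, size=n_tips - 2))
    node_ages = np.concatenate([inner, [root_age]])
    active = list(range(n_tips))
    for j, age in enumerate(node_ages):
        new = n_tips + j
        i1, i2 = rng.choice(len(active), size=2, replace=False)
        a, b = active[i1], active[i2]
        parent[a] = new
        parent[b] = new
        ages[new] = age
        active = [x for x in active if x not in (a, b)] + [new]
    return TimeTree(list(tip_names), parent, ages)


def simulate_alignment(
    tree: TimeTree,
    rates: LocusRates,
    subst: SubstModelSpec,
    sites,
    seed=None,
) -> Alignment:
    """Evolve one partition per locus down the tree.

    ``sites`` is an int (single locus) or a sequence of per-locus site
    counts matching ``rates``.  Branch length = locus branch rate x branch
    duration; sites evolve independently, each with its own discrete-gamma
    rate category when the substitution model has one.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(sites):
        sites = [int(sites)]
    sites = [int(s) for s in sites]
    if len(sites) != rates.branch_rates.shape[0]:
        raise ValueError("one site count per locus required")
    lam, u, uinv = _hky_eigen(subst.kappa, np.asarray(subst.pi))
    cat_rates = subst.rate_categories()
    durations = tree.branch_durations()
    branches = tree.branches()
    order = sorted(range(len(branches)), key=lambda k: -tree.ages[branches[k][1]])

    blocks = []
    for locus, n_sites in enumerate(sites):
        blens = rates.branch_rates[locus] * durations
        site_cat = rng.integers(0, len(cat_rates), size=n_sites)
        states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
        root = tree.root
        states[root] = rng.choice(4, size=n_sites, p=np.asarray(subst.pi))
        for k in order:
            child, par = branches[k]
            # transition matrices per category for this branch
            for c, r in enumerate(cat_rates):
                pmat = (u * np.exp(lam * blens[k] * r)) @ uinv
                pmat = np.clip(pmat, 0, None)
                pmat /= pmat.sum(axis=1, keepdims=True)
                mask = site_cat == c
                if not np.any(mask):
                    continue
                src = states[par, mask]
                draw = np.empty(mask.sum(), dtype=np.int8)
                for s in range(4):
                    rows = src == s
                    if np.any(rows):
                        draw[rows] = rng.choice(4, size=int(rows.sum()), p=pmat[s])
                states[child, mask] = draw
        blocks.append(states[: tree.n_tips])
    matrix = np.concatenate(blocks, axis=1)
    part_index = np.concatenate(
        [np.full(s, i, dtype=int) for i, s in enumerate(sites)]
    )
    names = [f"part{i+1}" for i in range(len(sites))]
    return Alignment(list(tree.tip_names), matrix, part_index, names)


def simulate_dataset(recipe: SimulationRecipe):
    """Full generative draw: tree, branch rates, alignment.

    Returns ``(tree, rates, alignment)``; identical seeds give identical
    output.
    """
    rng = np.random.default_rng(recipe.seed)
    tree = simulate_timetree(recipe.n_tips, recipe.root_age, seed=rng.integers(2**31))
    rates = simulate_branch_rates(
        recipe.clock,
        tree,
        n_loci=len(recipe.sites_per_partition),
        seed=rng.integers(2**31),
        mu=recipe.mu,
        sigma2=recipe.sigma2,
    )
    aln = simulate_alignment(
        tree, rates, recipe.subst, recipe.sites_per_partition, seed=rng.integers(2**31)
    )
    return tree, rates, aln


def mask_missing(aln: Alignment, fraction: float, seed=None) -> Alignment:
    """Replace a random fraction of cells with fully ambiguous states, to
    emulate patchy real alignments."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0,1)")
    rng = np.random.default_rng(seed)
    matrix = aln.matrix.copy()
    mask = rng.uniform(size=matrix.shape) < fraction
    matrix[mask] = -1
    return Alignment(list(aln.names), matrix, aln.partition_index.copy(), list(aln.partition_names))
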