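"""Sequential (two-step) Bayesian dating and posterior diagnostics.

Two-step dating: the marginal posterior node ages from a first, genome-scale
data set are refit as skew-t densities and attached as calibrations for a
second analysis of an independent data set.  Because the posterior under the
joint data factorizes as prior x lik1 x lik2, using the step-1 posterior as
the step-2 prior reproduces the joint posterior exactly - up to the
deliberate approximation of replacing the correlated multivariate posterior
by the product of its fitted marginals (with ancestor-descendant truncation
restored by the joint time prior).

Also here: the infinite-sites regression (posterior CI width against
posterior mean age, through the origin) and the report contrasting each
user calibration density with its marginal prior after truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrations import FixedAge, SkewT, fit_skew_t_ml
from .time_prior import TimePriorSpec, sample_time_prior
from .treeio import CalibratedTree, Trace

__all__ = [
    "posterior_to_calibrations",
    "infinite_sites_regression",
    "InfiniteSitesPoint",
    "prior_truncation_report",
]


def posterior_to_calibrations(
    trace: Trace, node_map: dict[str, int], seed: int = 0
) -> dict[int, SkewT]:
    """Fit a skew-t to each mapped trace column of posterior ages.

    ``node_map`` sends a trace column name (e.g. ``t_n4``) to the node index
    it calibrates in the target tree.  Near-degenerate columns yield a
    flagged (non-converged) fit but never an exception.
    """
    out: dict[int, SkewT] = {}
    for col, node in node_map.items():
        if col not in trace.columns:
            raise KeyError(f"trace has no column {col!r}")
        fit = fit_skew_t_ml(trace[col], seed=seed)
        out[node] = fit.density
    return out


@dataclass
class InfiniteSitesPoint:
    node: str
    mean_age: float
    ci_width: float
    subset: str = "all"


def infinite_sites_regression(points) -> tuple[float, float]:
    """Regression through the origin of CI width on posterior mean age.

    Returns (slope, Pearson correlation).  On the infinite-data limit the
    points fall on a line through the origin whose slope is the fossil-driven
    uncertainty per unit of divergence time; curvature or scatter indicates
    the sequence data still limit precision.  With fewer than 2 distinct
    points the correlation is undefined and returned as NaN.
    """
    pts = list(points)
    if len(pts) < 1:
        raise ValueError("need at least one point")
    t = np.array([p.mean_age if isinstance(p, InfiniteSitesPoint) else p[0] for p in pts], float)
    w = np.array([p.ci_width if isinstance(p, InfiniteSitesPoint) else p[1] for p in pts], float)
    if np.all(t == 0):
        raise ValueError("all mean ages are zero")
    slope = float(np.sum(w * t) / np.sum(t * t))
    if len(pts) < 2 or np.std(t) == 0 or np.std(w) == 0:
        r = math.nan
    else:
        r = float(np.corrcoef(t, w)[0, 1])
    return slope, r


def prior_truncation_report(
    ctree: CalibratedTree,
    spec: TimePriorSpec | None = None,
    n: int = 20000,
    seed: int = 0,
    iterations: int | None = None,
) -> pd.DataFrame:
    """Compare each calibration density with its marginal prior.

    Runs a prior-only MCMC and reports, per internal node, the 2.5/50/97.5%
    quantiles of the user density (where one exists) and of the sampled
    marginal prior, plus the maximum relative quantile shift.  Large shifts
    flag calibrations reshaped by truncation against their neighbours.
    """
    if spec is None:
        spec = TimePriorSpec.for_tree(ctree)
    trace = sample_time_prior(
        ctree, spec, n, seed=seed, iterations=iterations or max(4 * n, 20000)
    )
    qs = (0.025, 0.5, 0.975)
    rows = []
    for node in ctree.tree.internal_nodes:
        col = f"t_n{node}"
        samples = trace[col]
        marg = [float(np.quantile(samples, q)) for q in qs]
        d = spec.calibrations.get(node)
        if d is None or isinstance(d, FixedAge):
            user = [math.nan] * 3
            score = math.nan
        else:
            user = [d.quantile(q) for q in qs]
            score = max(
                abs(m - u) / abs(u) for m, u in zip(marg, user) if u != 0
            )
        rows.append(
            {
                "node": f"n{node}",
                "calibration": repr(d) if d is not None else "",
                "user_q2.5": user[0],
                "user_q50": user[1],
                "user_q97.5": user[2],
                "prior_q2.5": marg[0],
                "prior_q50": marg[1],
                "prior_q97.5": marg[2],
                "discrepancy": score,
            }
        )
    return pd.DataFrame(rows).set_index("node")
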