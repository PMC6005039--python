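import math

import numpy as np
import pytest
from scipy import stats

from chronodate import ClockModelSpec, LocusRates, simulate_branch_rates, simulate_timetree
from chronodate.clock_models import branch_rate_logprior, locus_hyperprior_logpdf


@pytest.fixture
def tree4():
    tree = simulate_timetree(4, root_age=1.0, seed=42)
    return tree


class TestBranchRatePrior:
    def test_sc_is_a_point_mass(self, tree4):
        spec = ClockModelSpec("SC", rate_prior=(2, 40))
        rates = LocusRates([0.05], [0.0], np.full((1, 6), 0.05))
        assert branch_rate_logprior(spec, tree4, rates) == 0.0
        bad = LocusRates([0.05], [0.0], np.full((1, 6), 0.06))
        with pytest.raises(ValueError):
            branch_rate_logprior(spec, tree4, bad)

    def test_ir_mean_preserving_correction(self, tree4):
        # E[r] = mu exactly because of the -sigma^2/2 shift of the log-mean
        spec = ClockModelSpec("IR", sigma2_prior=(1, 10))
        draws = np.array(
            [
                simulate_branch_rates(spec, tree4, seed=s, mu=1.0, sigma2=0.04)
                .branch_rates[0, 0]
                for s in range(4000)
            ]
        )
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_ar_variance_adds_along_paths(self, tree4):
        """Log-rate variance after two consecutive branches equals
        sigma^2 (dt1 + dt2): geometric Brownian motion is additive."""
        spec = ClockModelSpec("AR", sigma2_prior=(1, 10))
        sigma2 = 0.5
        # find a tip whose path from the root has two branches
        logr = []
        for s in range(6000):
            lr = simulate_branch_rates(spec, tree4, seed=s, mu=1.0, sigma2=sigma2)
            logr.append(np.log(lr.branch_rates[0]))
        logr = np.array(logr)
        durations = tree4.branch_durations()
        pos = {c: k for k, (c, _) in enumerate(tree4.branches())}
        # pick a branch whose parent is not the root; accumulate the full
        # root-to-branch path duration
        child = next(c for c, p in tree4.branches() if p != tree4.root)
        total_dt = 0.0
        node = child
        while node != tree4.root:
            total_dt += durations[pos[node]]
            node = int(tree4.parent[node])
        var = logr[:, pos[child]].var()
        se = var * math.sqrt(2 / logr.shape[0])
        assert abs(var - sigma2 * total_dt) < 4 * se

    def test_ar_short_branch_tracks_parent(self, tree4):
        spec = ClockModelSpec("AR", sigma2_prior=(1, 10))
        tree = tree4.copy()
        # squeeze one internal branch to near-zero duration
        inner = [n for n in tree.internal_nodes if n != tree.root][0]
        tree.ages[inner] = tree.ages[tree.parent[inner]] - 1e-9
        lr = simulate_branch_rates(spec, tree, seed=0, mu=1.0, sigma2=0.5)
        pos = {c: k for k, (c, _) in enumerate(tree.branches())}
        parent_rate = (
            1.0 if tree.parent[inner] == tree.root
            else lr.branch_rates[0, pos[int(tree.parent[inner])]]
        )
        assert lr.branch_rates[0, pos[inner]] == pytest.approx(parent_rate, rel=1e-3)

    def test_density_simulator_agreement_ir(self):
        """Simulator draws binned against the density branch_rate_logprior
        assigns (chi-square, 20 equal-mass bins): the two routes agree."""
        tree2 = simulate_timetree(2, root_age=1.0, seed=0)
        spec = ClockModelSpec("IR", sigma2_prior=(1, 10))
        mu, s2 = 1.0, 0.25
        # loci are i.i.d. given fixed (mu, sigma2): one call gives the sample
        lr = simulate_branch_rates(spec, tree2, n_loci=100000, seed=1, mu=mu, sigma2=s2)
        draws = lr.branch_rates[:, 0]
        edges = np.quantile(draws, np.linspace(0, 1, 21))
        edges[0], edges[-1] = 1e-9, np.inf
        counts, _ = np.histogram(draws, bins=edges)

        # density route: branch_rate_logprior as a function of one branch
        # rate with the other held fixed, normalized on a grid
        rfix = 1.0

        def logdens(v):
            rates = LocusRates([mu], [s2], np.array([[v, rfix]]))
            return branch_rate_logprior(spec, tree2, rates)

        grid = np.linspace(1e-4, 12.0, 8001)
        dens = np.exp([logdens(v) for v in grid])
        dens /= np.trapezoid(dens, grid)
        cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        probs = np.diff(np.interp(np.clip(edges, grid[0], grid[-1]), grid, cdf))
        probs[-1] = 1 - probs[:-1].sum()
        chi2 = float(np.sum((counts - draws.size * probs) ** 2 / (draws.size * probs)))
        assert stats.chi2(df=19).sf(chi2) > 0.01

    def test_sc_is_small_sigma_limit(self, tree4):
        ir = ClockModelSpec("IR", sigma2_prior=(1, 10))
        lr = simulate_branch_rates(ir, tree4, seed=1, mu=0.05, sigma2=1e-6)
        assert np.allclose(lr.branch_rates, 0.05, rtol=1e-2)
        ar = ClockModelSpec("AR", sigma2_prior=(1, 10))
        lr = simulate_branch_rates(ar, tree4, seed=2, mu=0.05, sigma2=1e-6)
        assert np.allclose(lr.branch_rates, 0.05, rtol=1e-2)

    def test_ar_sister_branch_correlation_positive(self):
        """Sister branches share their parent's rate history, so their
        log-rates are positively correlated under AR (sign test)."""
        spec = ClockModelSpec("AR", sigma2_prior=(1, 10))
        wins = 0
        n = 300
        for s in range(n):
            tree = simulate_timetree(4, root_age=1.0, seed=s)
            lr = simulate_branch_rates(spec, tree, seed=10000 + s, mu=1.0, sigma2=0.5)
            pos = {c: k for k, (c, _) in enumerate(tree.branches())}
            # a non-root internal node and its sibling subtree share history
            logr = np.log(lr.branch_rates[0])
            # correlation proxy: deviation products of the two children of
            # the deepest internal node
            deepest = max(
                (nd for nd in tree.internal_nodes if nd != tree.root),
                key=lambda nd: tree.ages[nd],
                default=None,
            )
            if deepest is None:
                continue
            kids = tree.children(deepest)
            prod = (logr[pos[kids[0]]]) * (logr[pos[kids[1]]])
            wins += prod > 0
        # under independence P(same sign of centred log-rates) ~ 0.5
        assert wins / n > 0.55


class TestHyperprior:
    def test_single_locus_reduces_to_gamma(self):
        spec = ClockModelSpec("SC", rate_prior=(2, 40))
        lp = locus_hyperprior_logpdf(spec, [0.05])
        assert lp == pytest.approx(stats.gamma.logpdf(0.05, 2, scale=1 / 40))

    def test_mean_rate_follows_its_gamma(self):
        spec = ClockModelSpec("SC", rate_prior=(2, 40), hyperprior_mode="gamma_dirichlet")
        draws = [
            simulate_branch_rates(spec, simulate_timetree(3, seed=0), n_loci=3, seed=s).mu.mean()
            for s in range(4000)
        ]
        draws = np.array(draws)
        assert abs(draws.mean() - 0.05) < 4 * draws.std() / math.sqrt(draws.size)
        assert stats.kstest(draws, stats.gamma(2, scale=1 / 40).cdf).pvalue > 0.01

    def test_permutation_symmetry(self):
        spec = ClockModelSpec("IR", rate_prior=(2, 8), sigma2_prior=(1, 10))
        mu = np.array([0.1, 0.3, 0.2])
        s2 = np.array([0.05, 0.2, 0.1])
        lp1 = locus_hyperprior_logpdf(spec, mu, s2)
        lp2 = locus_hyperprior_logpdf(spec, mu[::-1], s2[::-1])
        assert lp1 == pytest.approx(lp2, abs=1e-12)

    def test_density_is_proper_change_of_variables(self):
        """Monte-Carlo check: average of exp(logpdf) over a grid region
        equals the simulated frequency for L=2 loci."""
        spec = ClockModelSpec("SC", rate_prior=(2, 2), hyperprior_mode="gamma_dirichlet")
        rng = np.random.default_rng(3)
        mean = rng.gamma(2, 0.5, size=200000)
        props = rng.dirichlet([1, 1], size=200000)
        mus = 2 * mean[:, None] * props
        # empirical frequency of a box vs integral of the density
        box = (mus[:, 0] > 0.5) & (mus[:, 0] < 1.0) & (mus[:, 1] > 0.5) & (mus[:, 1] < 1.0)
        freq = box.mean()
        grid = np.linspace(0.5, 1.0, 60)
        h = grid[1] - grid[0]
        total = 0.0
        for a in grid[:-1] + h / 2:
            for b in grid[:-1] + h / 2:
                total += math.exp(locus_hyperprior_logpdf(spec, [a, b])) * h * h
        assert total == pytest.approx(freq, rel=0.05)

    def test_length_mismatch_rejected(self):
        spec = ClockModelSpec("IR", sigma2_prior=(1, 10))
        with pytest.raises(ValueError, match="length"):
            locus_hyperprior_logpdf(spec, [0.1, 0.2], [0.1])
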