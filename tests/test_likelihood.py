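import io
import itertools
import math

import numpy as np
import pytest

from chronodate import (
    ClockModelSpec,
    SubstModelSpec,
    approx_loglik,
    build_branch_approx,
    exact_loglik,
    read_alignment,
    read_calibrated_newick,
    simulate_alignment,
    simulate_branch_rates,
)
from chronodate.likelihood import PartitionLikelihood, _hky_eigen, discrete_gamma_rates


def jc_p_same(t):
    return 0.25 + 0.75 * math.exp(-4 * t / 3)


@pytest.fixture
def tree2():
    return read_calibrated_newick("(A:0.5,B:0.5);").tree


class TestExact:
    def test_identical_one_site_zero_lengths(self, tree2, jc):
        aln = read_alignment(io.StringIO(">A\nA\n>B\nA\n"))
        assert exact_loglik(aln, tree2, [0.0, 0.0], jc) == pytest.approx(math.log(0.25))

    def test_two_tip_jc_closed_form(self, tree2, jc):
        """Pairwise JC likelihood equals the closed-form transition
        probability applied per site, over random branch lengths/data."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            b = rng.uniform(0.01, 1.0, size=2)
            t = b.sum()
            seqs = rng.integers(0, 4, size=(2, 30))
            code = "ACGT"
            text = f">A\n{''.join(code[s] for s in seqs[0])}\n>B\n{''.join(code[s] for s in seqs[1])}\n"
            aln = read_alignment(io.StringIO(text))
            expected = 0.0
            for x, y in seqs.T:
                p = jc_p_same(t) if x == y else (1 - jc_p_same(t)) / 3
                expected += math.log(0.25 * p)
            assert exact_loglik(aln, tree2, b, jc) == pytest.approx(expected, rel=1e-12)

    def test_pruning_equals_brute_force_hky_gamma(self, hky_g4, small_alignment):
        tree = read_calibrated_newick("((A:0.1,B:0.2):0.1,(C:0.15,D:0.25):0.05);").tree
        blens = np.array([0.1, 0.2, 0.15, 0.25, 0.1, 0.05])
        got = exact_loglik(small_alignment, tree, blens, hky_g4)
        lam, u, uinv = _hky_eigen(hky_g4.kappa, np.asarray(hky_g4.pi))
        rates = discrete_gamma_rates(hky_g4.gamma_shape, 4)
        pi = np.asarray(hky_g4.pi)
        rows = {nm: small_alignment.matrix[small_alignment.names.index(nm)]
                for nm in tree.tip_names}
        total = 0.0
        for site in range(small_alignment.n_sites):
            site_l = 0.0
            for r in rates:
                pmats = {c: (u * np.exp(lam * b * r)) @ uinv
                         for (c, _), b in zip(tree.branches(), blens)}
                acc = 0.0
                for anc in itertools.product(range(4), repeat=3):
                    state = {i: rows[tree.tip_names[i]][site] for i in range(4)}
                    state[4], state[5], state[6] = anc
                    pr = pi[state[tree.root]]
                    for c, p in tree.branches():
                        pr *= pmats[c][state[p], state[c]]
                    acc += pr
                site_l += acc / len(rates)
            total += math.log(site_l)
        assert got == pytest.approx(total, rel=1e-10)

    def test_reroot_invariance(self, jc):
        """A reversible model gives the same likelihood wherever the root
        sits along a branch (checked by sliding the root age)."""
        aln = read_alignment(
            io.StringIO(">A\nACGTACGTAA\n>B\nACTTACGAAA\n>C\nGCGTACGTAT\n")
        )
        tree = read_calibrated_newick("((A:0.3,B:0.3):0.2,C:0.5);").tree
        pos = {c: k for k, (c, _) in enumerate(tree.branches())}
        a, b, c = (tree.tip_names.index(nm) for nm in "ABC")
        inner = tree.mrca(["A", "B"])
        base = None
        for split in (0.1, 0.35, 0.6):
            # slide the root along the inner--C path (total length 0.7)
            blens = np.zeros(4)
            blens[pos[a]] = blens[pos[b]] = 0.3
            blens[pos[inner]] = split
            blens[pos[c]] = 0.7 - split
            ll = exact_loglik(aln, tree, blens, jc)
            if base is None:
                base = ll
            assert ll == pytest.approx(base, abs=1e-9)

    def test_hky_kappa1_equals_jc(self, small_alignment):
        tree = read_calibrated_newick("((A:0.1,B:0.2):0.1,(C:0.15,D:0.25):0.05);").tree
        blens = np.array([0.1, 0.2, 0.15, 0.25, 0.1, 0.05])
        hky = SubstModelSpec("HKY", kappa=1.0, pi=(0.25, 0.25, 0.25, 0.25))
        jc = SubstModelSpec("JC")
        assert exact_loglik(small_alignment, tree, blens, hky) == pytest.approx(
            exact_loglik(small_alignment, tree, blens, jc), rel=1e-12
        )

    def test_partitions_factorize(self, jc):
        tree = read_calibrated_newick("((A:0.2,B:0.2):0.2,C:0.4);").tree
        text = ">A\nACGTAC\n>B\nACTTAC\n>C\nGCGTAT\n"
        whole = read_alignment(io.StringIO(text))
        split = read_alignment(io.StringIO(text), partitions=[(1, 3), (4, 6)])
        b = np.array([0.2, 0.2, 0.4, 0.2])
        total = exact_loglik(whole, tree, b, jc)
        parts = sum(
            PartitionLikelihood(split, tree, jc, partition=p).loglik(b) for p in (0, 1)
        )
        assert parts == pytest.approx(total, rel=1e-12)

    def test_missing_species_equivalent_to_pruning(self, jc):
        """A species that is all-ambiguous in a partition contributes
        nothing: likelihood equals that of the tree without it."""
        tree3 = read_calibrated_newick("((A:0.2,B:0.2):0.2,C:0.4);").tree
        aln3 = read_alignment(io.StringIO(">A\nACGT\n>B\nACTT\n>C\n????\n"))
        ll3 = exact_loglik(aln3, tree3, np.array([0.2, 0.2, 0.4, 0.2]), jc)
        tree2 = read_calibrated_newick("(A:0.3,B:0.3);").tree
        aln2 = read_alignment(io.StringIO(">A\nACGT\n>B\nACTT\n"))
        ll2 = exact_loglik(aln2, tree2, np.array([0.2, 0.2]), jc)
        assert ll3 == pytest.approx(ll2, rel=1e-12)

    def test_unmatched_tip_rejected(self, jc, small_alignment):
        tree = read_calibrated_newick("((A:0.1,B:0.2):0.1,(C:0.15,X:0.25):0.05);").tree
        with pytest.raises(ValueError, match="X"):
            exact_loglik(small_alignment, tree, np.full(6, 0.1), jc)


class TestApprox:
    @pytest.fixture
    def sim_partition(self, rooted_calibrated4, jc):
        tree = rooted_calibrated4.tree
        clock = ClockModelSpec("SC", rate_prior=(2, 4))
        rates = simulate_branch_rates(clock, tree, 1, seed=5, mu=0.3)
        aln = simulate_alignment(tree, rates, jc, 1000, seed=6)
        true_b = rates.branch_rates[0] * tree.branch_durations()
        return aln, tree, true_b

    def test_mle_near_truth_and_stationarity(self, sim_partition, jc):
        aln, tree, true_b = sim_partition
        ap = build_branch_approx(aln, tree, jc)
        assert ap.converged and ap.has_variable_sites
        # only the sum of the two root-adjacent branch lengths is
        # identifiable on a rooted reversible tree: compare the sum there,
        # each branch individually elsewhere, with conditional SEs
        se = 1.0 / np.sqrt(-np.diag(ap.hessian))
        root_kids = {c for c, p in tree.branches() if p == tree.root}
        for k, (child, _) in enumerate(tree.branches()):
            if child in root_kids:
                continue
            assert abs(ap.b_hat[k] - true_b[k]) < 3 * max(se[k], 1e-3)
        pair = [k for k, (c, _) in enumerate(tree.branches()) if c in root_kids]
        got = ap.b_hat[pair].sum()
        want = true_b[pair].sum()
        assert abs(got - want) < 3 * max(np.hypot(*se[pair]), 1e-3)
        assert np.max(np.abs(ap.gradient)) < 1e-3
        # negative semidefinite up to finite-difference noise on the
        # confounded (null) direction, relative to the curvature scale
        evals = np.linalg.eigvalsh(ap.hessian)
        assert np.max(evals) <= 1e-6 * np.abs(evals).max()

    def test_quadratic_exact_at_optimum_and_near(self, sim_partition, jc):
        aln, tree, true_b = sim_partition
        ap = build_branch_approx(aln, tree, jc)
        assert approx_loglik(ap, ap.b_hat) == pytest.approx(ap.loglik_at_max, abs=1e-12)
        pl = PartitionLikelihood(aln, tree, jc)
        rng = np.random.default_rng(7)
        # conditional (per-coordinate) SEs: the two root-adjacent branches are
        # confounded on a rooted reversible tree, so marginal SEs are unbounded
        se = 1.0 / np.sqrt(-np.diag(ap.hessian))
        for _ in range(5):
            b = np.clip(ap.b_hat + rng.uniform(-2, 2, size=se.size) * se, 1e-6, None)
            assert abs(approx_loglik(ap, b) - pl.loglik(b)) < 1.0

    def test_far_from_optimum_stays_finite(self, sim_partition, jc):
        aln, tree, _ = sim_partition
        ap = build_branch_approx(aln, tree, jc)
        val = approx_loglik(ap, ap.b_hat * 5)
        assert np.isfinite(val)

    def test_dimension_mismatch_rejected(self, sim_partition, jc):
        aln, tree, _ = sim_partition
        ap = build_branch_approx(aln, tree, jc)
        with pytest.raises(ValueError, match="dimension"):
            approx_loglik(ap, ap.b_hat[:-1])


def test_discrete_gamma_categories_average_to_one():
    for shape in (0.2, 0.7, 1.5, 10.0):
        rates = discrete_gamma_rates(shape, 4)
        assert rates.mean() == pytest.approx(1.0, rel=1e-10)
        assert np.all(np.diff(rates) > 0)
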