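import io

import numpy as np
import pytest

from chronodate import (
    CalibratedTree,
    ClockModelSpec,
    PartitionLikelihood,
    SubstModelSpec,
    parse_calibration,
    read_alignment,
    read_calibrated_newick,
    simulate_alignment,
    simulate_branch_rates,
)
from chronodate.time_prior import TimePriorSpec


@pytest.fixture
def pectinate4():
    """4-tip ladder tree with node ages 0.25 < 0.55 < 1.0 (100 My units)."""
    ct = read_calibrated_newick("(((A,B),C),D);")
    ct.tree.ages[[4, 5, 6]] = [0.25, 0.55, 1.0]
    return ct


@pytest.fixture
def rooted_calibrated4(pectinate4):
    ct = pectinate4
    ct.calibrations[ct.tree.root] = parse_calibration("B(0.9,1.1,0.025,0.025)")
    return ct


@pytest.fixture
def hky_g4():
    return SubstModelSpec("HKY", kappa=4.0, pi=(0.3, 0.2, 0.2, 0.3), gamma_shape=1.0, ncat=4)


@pytest.fixture
def jc():
    return SubstModelSpec("JC")


@pytest.fixture
def small_alignment():
    text = ">A\nACGTG\n>B\nACATG\n>C\nGCGTA\n>D\nACGCC\n"
    return read_alignment(io.StringIO(text))


def make_sc_dataset(ctree, model, mu=0.3, sites=1000, seed=0):
    """Simulate one strict-clock partition on a calibrated tree."""
    clock = ClockModelSpec("SC", rate_prior=(2, 4))
    rates = simulate_branch_rates(clock, ctree.tree, 1, seed=seed, mu=mu)
    aln = simulate_alignment(ctree.tree, rates, model, sites, seed=seed + 1)
    return clock, rates, aln


@pytest.fixture
def sc_setup(rooted_calibrated4, jc):
    ct = rooted_calibrated4
    clock, rates, aln = make_sc_dataset(ct, jc, seed=11)
    spec = TimePriorSpec.for_tree(ct)
    like = PartitionLikelihood(aln, ct.tree, jc)
    return ct, spec, clock, rates, aln, like
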