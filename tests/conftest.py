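import random

import pytest

from trlocus.evaluation import annotate_simulated
from trlocus.simulate import SimConfig, simulate_locus


@pytest.fixture(scope="session")
def small_sim():
    """A modest defect-free locus with duplication, inversion and contigs."""
    return simulate_locus(
        SimConfig(seed=11, n_subgroups=5, genes_per_subgroup=(3, 4), j_block=(6, 2), n_nonlocalized=2)
    )


@pytest.fixture(scope="session")
def small_annotated(small_sim):
    return annotate_simulated(small_sim)


@pytest.fixture(scope="session")
def recovery_loci():
    """Twenty defect-free loci of ~100 genes each, annotated, with truth."""
    out = []
    for k in range(20):
        sim = simulate_locus(
            SimConfig(seed=9000 + k, n_subgroups=10, genes_per_subgroup=(4, 7),
                      j_block=(12, 2), n_nonlocalized=2)
        )
        out.append((sim, annotate_simulated(sim)))
    return out


@pytest.fixture
def rng():
    return random.Random(1234)
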