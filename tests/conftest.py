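import numpy as np
import pytest

from genrelate.align import ScoringScheme
from genrelate.simulate import EvolutionParams, evolve_genome, generate_ancestor


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def ancestor_20kb():
    return generate_ancestor(20_000, 0.5, seed=11, id="anc20k")


def diverged_pair(length, rate, seed, indel_rate=0.0):
    """A (genome, mutated copy, realized divergence) triple for tests."""
    anc = generate_ancestor(length, 0.5, seed=seed, id=f"anc{seed}")
    ev, d = evolve_genome(
        anc,
        EvolutionParams(
            substitution_rate=rate, indel_rate=indel_rate, seed=seed + 1000
        ),
    )
    return anc, ev, d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
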