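import numpy as np
import pytest

from netmd.contacts import ContactEventTable, ResidueId, build_vocabulary, to_occupancy
from netmd.synthetic import GeneratorSpec, generate_ensemble


def rid(num: int, chain: str = "A", name: str = "ALA") -> ResidueId:
    return ResidueId(chain=chain, residue_name=name, residue_number=num)


@pytest.fixture(scope="session")
def tiny_spec() -> GeneratorSpec:
    """Small two-system ensemble used by several integration tests."""
    return GeneratorSpec(
        n_systems=2,
        replicas_per_system=3,
        n_frames=80,
        length_jitter=8,
        n_residues=20,
        vocabulary_size=80,
        n_states=2,
        canonical_boundaries=(40,),
        condition_edges=10,
        outlier=None,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_spec):
    return generate_ensemble(tiny_spec)


@pytest.fixture(scope="session")
def tiny_occupancies(tiny_ensemble):
    tables, _ = tiny_ensemble
    vocab = build_vocabulary(tables)
    return [to_occupancy(t, vocab) for t in tables], vocab
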