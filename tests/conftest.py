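import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from atropomine.fixtures import (
    FamilySpec,
    NeighborhoodSpec,
    generate_family,
    generate_neighborhood,
)
from atropomine.seqprep import AMINO_ACIDS, ProteinSeq, ReferenceScheme


def random_protein(rng: np.random.Generator, length: int, pid: str = "p") -> ProteinSeq:
    return ProteinSeq(
        pid, "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240910)


@pytest.fixture(scope="session")
def reference_scheme():
    rng = np.random.default_rng(7)
    return ReferenceScheme(reference=random_protein(rng, 400, "ref"))


@pytest.fixture(scope="session")
def family():
    """A separable planted-signature family, shared across tests."""
    return generate_family(FamilySpec(seed=0))


@pytest.fixture(scope="session")
def neighborhood_fixture():
    """One synthetic P450 neighborhood with known truth."""
    return generate_neighborhood(NeighborhoodSpec(seed=11))
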