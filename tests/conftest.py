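import numpy as np
import pytest

from casarray import generate_benchmark_library, load_species_registry


@pytest.fixture(scope="session")
def registry():
    return load_species_registry()


@pytest.fixture(scope="session")
def lb_profile(registry):
    return registry["Lb"]


@pytest.fixture(scope="session")
def library51():
    return generate_benchmark_library(seed=1)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
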