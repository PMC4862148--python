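import numpy as np
import pytest

from pairtrim import AdapterPair, MatchModel, TrimParams, default_adapters


@pytest.fixture(scope="session")
def model() -> MatchModel:
    return MatchModel()


@pytest.fixture(scope="session")
def adapters() -> AdapterPair:
    return default_adapters()


@pytest.fixture(scope="session")
def params() -> TrimParams:
    return TrimParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160510)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
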