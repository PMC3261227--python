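import numpy as np
import pytest

import spsfinder as sf


@pytest.fixture(scope="session")
def suh():
    return sf.compile_pattern("YGTGRGAA", "SuH")


@pytest.fixture(scope="session")
def abox():
    return sf.compile_pattern("RCAGSTG", "Abox")


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def census_td():
    """Generated census contig for the stalk-eyed-fly-like architecture."""
    td, _ = sf.census_specs()
    rec, genes, truth = sf.generate_contig(td, seed=1)
    return str(rec.seq), genes, truth


@pytest.fixture(scope="session")
def census_dm():
    _, dm = sf.census_specs()
    rec, genes, truth = sf.generate_contig(dm, seed=2)
    return str(rec.seq), genes, truth
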