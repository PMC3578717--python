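import numpy as np
import pytest

from fluidms import DigestConfig, ProteinRecord, default_panel

AMINO = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def digest_cfg():
    return DigestConfig()


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = AMINO) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_record(accession: str, sequence: str, **kw) -> ProteinRecord:
    return ProteinRecord(accession=accession, name=accession, sequence=sequence, **kw)
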