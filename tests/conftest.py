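import numpy as np
import pytest

from episcan.config import PipelineConfig
from episcan.scales import builtin_scale
from episcan.secstruct import load_chou_fasman_params, load_gor_info
from episcan.seq_io import AMINO_ACIDS, ProteinSequence


@pytest.fixture(scope="session")
def config():
    return PipelineConfig.default()


@pytest.fixture(scope="session")
def hopp_woods():
    return builtin_scale("hopp-woods")


@pytest.fixture(scope="session")
def emini():
    return builtin_scale("emini-surface")


@pytest.fixture(scope="session")
def flex_scale():
    return builtin_scale("flexibility")


@pytest.fixture(scope="session")
def cf_params():
    return load_chou_fasman_params()


@pytest.fixture(scope="session")
def gor_info():
    return load_gor_info()


def random_protein(rng: np.random.Generator, length: int, seq_id: str = "random") -> ProteinSequence:
    return ProteinSequence(
        id=seq_id, residues="".join(rng.choice(list(AMINO_ACIDS), size=length))
    )
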