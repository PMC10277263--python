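import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from motifevo.motif_grammar import builtin_catalog

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_protein(rng, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))
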