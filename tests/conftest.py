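import numpy as np
import pytest

import isopocket as ip


@pytest.fixture(scope="session")
def table3():
    return ip.read_residue_table(ip.bundled_fixture("table3_active_site"))


@pytest.fixture(scope="session")
def table4():
    return ip.read_residue_table(ip.bundled_fixture("table4_cleft"))


@pytest.fixture
def rng():
    return np.random.default_rng(20)


@pytest.fixture(scope="session")
def default_params():
    return ip.AlignmentParams()


def random_peptide(rng, max_len=7, min_len=2) -> str:
    from isopocket.alignment import AMINO_ACIDS

    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))
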