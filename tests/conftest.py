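import numpy as np
import pytest

from lipodyn.intrinsic import ExchangeConditions
from lipodyn.peptides import PeptideRecord
from lipodyn.simulate import apoa1_sequence


@pytest.fixture(scope="session")
def apoa1() -> str:
    return apoa1_sequence()


@pytest.fixture(scope="session")
def conditions() -> ExchangeConditions:
    """Labeling conditions used throughout: pD 7.2, 0 degC."""
    return ExchangeConditions(pD=7.2, temperature=273.15)


@pytest.fixture(scope="session")
def peptide_e212(apoa1) -> PeptideRecord:
    """The 11-residue C-terminal-domain peptide E212-L222 (EDLRQGLLPVL)."""
    pep = PeptideRecord(apoa1[211:222], 212, 222)
    assert pep.sequence == "EDLRQGLLPVL"
    return pep


@pytest.fixture(scope="session")
def peptide_t161(apoa1) -> PeptideRecord:
    """A 12-residue peptide from the fast-exchanging LCAT-binding loop."""
    return PeptideRecord(apoa1[160:172], 161, 172)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
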