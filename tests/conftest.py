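import numpy as np
import pytest

import aptaswitch as ap
from aptaswitch.calibration import txtl_calibration
from aptaswitch.synthetic import _random_construct


#: CDS used throughout: start codon + enough codons for the footprint,
#: with a UCCUCC patch so realistic SD:CDS interactions occur.
CDS = "AUGGCUUCCUCCGAAGACGUUAUCAAA"

#: CDS with no C/G complementarity to anything upstream (A/G only after AUG)
INERT_CDS = "AUGAAAGAAAAAGGAAAAAGAAAAA"


@pytest.fixture(scope="session")
def calib():
    return ap.CalibrationParams()


@pytest.fixture(scope="session")
def txtl_calib():
    return txtl_calibration()


@pytest.fixture(scope="session")
def hairpin_aptamer():
    return ap.toy_aptamer("hairpin", 4, 4, kd=1e-7)


@pytest.fixture(scope="session")
def double_aptamer():
    return ap.toy_aptamer("double_hairpin", 4, 4, kd=187.7e-9)


@pytest.fixture(scope="session")
def simple_on_construct(hairpin_aptamer):
    """Aptamer far from an unstructured consensus SD: bound == unbound."""
    return ap.RiboswitchConstruct(
        "simple-on",
        "AAACAA",
        hairpin_aptamer,
        "AAGGAGGUAACAA",
        CDS,
        ap.Mode.ON,
    )


def random_constructs(aptamer, n, seed=0, modes=(ap.Mode.ON, ap.Mode.OFF)):
    rng = np.random.default_rng(seed)
    return [
        _random_construct(rng, aptamer, modes[k % len(modes)], k) for k in range(n)
    ]
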