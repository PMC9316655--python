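import numpy as np
import pytest

from specfid.spectra_io import Peak, SpectrumRecord


@pytest.fixture
def simple_record() -> SpectrumRecord:
    return SpectrumRecord(
        peaks=[Peak(120.05, 40.0), Peak(85.0, 100.0), Peak(200.1, 10.0)],
        inchikey="WQZGKKKJIJFFOK-GASJEMHNSA-N",
        smiles="OCC1OC(O)C(O)C(O)C1O",
        spectrum_id="spec-1",
        source="unit-test",
        ionization_mode="positive",
        adduct="[M+H]+",
        precursor_mz=181.0707,
        exact_mass=180.0634,
        instrument_type="Orbitrap",
        instrument="Q Exactive",
        collision_energy_raw="35 eV",
        collision_energy_ev=35.0,
        mass_accuracy=5.0,
        library="test-lib",
        external_ids="HMDB0000122",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


MSP_TWO_ENTRIES = """\
Name: alpha
InChIKey: AAAAAAAAAAAAAA-BBBBBBBBBB-N
PrecursorMZ: 181.0707
Ion_mode: P
Num Peaks: 3
100.1 50
99.2 10
120.5 33

Name: beta
PrecursorMZ: 250.1
Ion_mode: N
Num Peaks: 5
50 1
60 2
70.7 3
80 4
90 5
"""


@pytest.fixture
def msp_two_entries() -> str:
    return MSP_TWO_ENTRIES
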