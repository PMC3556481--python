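import pytest

from glycoforge import (
    TN_ALPHABET,
    TN_STN_ALPHABET,
    EnumerationSpec,
    PeptideSequence,
    identify_glycosites,
    make_tandem_repeat,
)

#: The two phases of the MUC1 20-aa tandem-repeat unit.
MUC1_UNIT_RP = "RPAPGSTAPPAHGVTSAPDT"
MUC1_UNIT_HG = "HGVTSAPDTRPAPGSTAPPA"


@pytest.fixture
def muc1_unit():
    return PeptideSequence(MUC1_UNIT_RP, id="MUC1_TR")


@pytest.fixture
def muc1_sites(muc1_unit):
    return tuple(identify_glycosites(muc1_unit))


@pytest.fixture
def tn_spec(muc1_sites):
    return EnumerationSpec(sites=muc1_sites, alphabet=TN_ALPHABET)


@pytest.fixture
def tn_stn_spec(muc1_sites):
    return EnumerationSpec(sites=muc1_sites, alphabet=TN_STN_ALPHABET)


@pytest.fixture
def muc1_protein(muc1_unit):
    return make_tandem_repeat(muc1_unit, copies=3, id="MUC1_3x")
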