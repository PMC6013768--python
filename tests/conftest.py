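import pytest

from passportseq.panel_design import MirSNP, design_panel
from passportseq.seed_scan import MiRNA
from passportseq.simulate import make_barcode_plan, simulate_panel


@pytest.fixture
def mirna():
    # seed (positions 2-8) = GGAAUGU; its mRNA complement is ACATTCC
    return MiRNA("miR-X", "UGGAAUGUAAAGAAGUAUGUAU")


@pytest.fixture
def simple_snp():
    return MirSNP(
        snp_id="rs0001",
        ref_allele="G",
        alt_allele="T",
        flank5="A" * 22,
        flank3="C" * 9,
    )


@pytest.fixture
def small_panel():
    return simulate_panel(6, seed=42)


@pytest.fixture
def small_library(small_panel):
    return design_panel(small_panel)


@pytest.fixture
def small_sheet():
    return make_barcode_plan(2, ["HEK293", "HeLa"], 2, seed=7)
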