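import numpy as np
import pytest

from phosflow.io import ChannelMap, PSMRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_psm(
    scan_id="scan_1",
    sequence="SVYTEIK",
    sites=(("Y", 3, 0.99),),
    ion_score=40.0,
    interference=5.0,
    fdr=1e-4,
    tmt=(2000.0,) * 6,
    transgenic=False,
    gene="Siglecf",
):
    return PSMRecord(
        scan_id=scan_id,
        sequence=sequence,
        proteins=("P12345",),
        gene_symbols=(gene,),
        phospho_positions=tuple(sites),
        ion_score=ion_score,
        isolation_interference=interference,
        percolator_fdr=fdr,
        tmt_intensities=np.array(tmt, dtype=float),
        is_transgenic=transgenic,
    )


@pytest.fixture
def psm_factory():
    return make_psm


@pytest.fixture
def six_plex_map():
    return ChannelMap(
        tuple(f"TMT_{i}" for i in range(1, 7)),
        tuple(f"mouse_{i}" for i in range(1, 7)),
        ("disease",) * 3 + ("control",) * 3,
    )
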