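import pytest

from sgc import (
    build_earray,
    ice_balance,
    insulation_cids,
    integrate_ura3,
    make_synxiil_fixture,
    make_synxiil_hic,
    make_toy_chromosome,
)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def synxiil():
    """The synXIIL-like reference arm (46 LUs, 170 kbp, 81 genes)."""
    return make_synxiil_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def synxiil_lu24(synxiil):
    """Arm with URA3 integrated by chunk-splitting LU-24 into 24-a/b/c."""
    return integrate_ura3(synxiil, "LU-24", "chunk_split")


@pytest.fixture(scope="session")
def earray(synxiil):
    """Episomal array of the 10 essential genes from the first 140 kbp."""
    return build_earray(synxiil, 140_000)


@pytest.fixture(scope="session")
def synxiil_cids(synxiil_lu24):
    """Balanced synthetic contact map + detected CID segmentation for the
    URA3-integrated arm, plus the planted boundary bins."""
    mat, planted = make_synxiil_hic(synxiil_lu24, seed=FIXTURE_SEED, noise=0.05)
    cids = insulation_cids(ice_balance(mat))
    return mat, cids, planted


@pytest.fixture()
def toy3():
    """3 equal LUs, no essential genes, centromere outside the region,
    URA3 in the middle LU."""
    return make_toy_chromosome(3, essential_lus=(), ura3_lu=2)


@pytest.fixture()
def toy5_cen3():
    """5 LUs with the centromere inside LU-3."""
    return make_toy_chromosome(5, centromere_lu=3, ura3_lu=5)
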