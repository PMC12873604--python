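import pytest

from telocus import SimConfig, simulate_all
from telocus.annotation import GenomicInterval, TECatalog, TEElement


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic dataset, generated once per session."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default fixture bundle written to disk once per session."""
    from telocus import write_fixture_bundle

    out = tmp_path_factory.mktemp("fixture")
    write_fixture_bundle(SimConfig(seed=1), out)
    return out


def make_element(locus_id="L1HS_x", chrom="chr1", start=1000, end=8000,
                 strand="+", te_class="L1", subfamily="L1HS", age_rank=0,
                 full_length=False):
    return TEElement(locus_id, GenomicInterval(chrom, start, end, strand),
                     te_class, subfamily, age_rank, full_length)


@pytest.fixture
def tiny_catalog():
    """Six elements on two chromosomes, mixed classes and ages."""
    elements = [
        make_element("L1HS_1", "chr1", 1_000, 8_000, "+", "L1", "L1HS", 0, True),
        make_element("L1PA2_1", "chr1", 20_000, 27_000, "-", "L1", "L1PA2", 1, True),
        make_element("L1PA3_1", "chr2", 5_000, 11_500, "+", "L1", "L1PA3", 2, True),
        make_element("AluY_1", "chr1", 40_000, 40_300, "+", "Alu", "AluY", 10_000),
        make_element("AluY_2", "chr2", 1_000, 1_310, "-", "Alu", "AluY", 10_000),
        make_element("SVA_A_1", "chr2", 50_000, 51_400, "+", "SVA", "SVA_A", 10_000),
    ]
    return TECatalog(elements, age_order=["L1HS", "L1PA2", "L1PA3"])
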