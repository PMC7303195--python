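import numpy as np
import pytest

from spatialeqtl.fragments import GeneModel, Variant
from spatialeqtl.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def planted_config() -> SyntheticConfig:
    """Three planted links, zero background contacts, seed frozen."""
    return SyntheticConfig(
        seed=0,
        planted_links=[(0, 0, 0, 0.5), (1, 1, 1, -0.7), (2, 2, 2, 0.3)],
        ld_blocks=[[0, 1, 2]],
        motif_disruptions=[(0, "MOTIF_NEG", "-"), (1, "MOTIF_POS", "+")],
        planted_marks=[(0, "adipose", "H3K27ac"), (0, "adipose", "H3K4me3")],
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return generate_dataset(planted_config)


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel(
            gene_id="G1",
            chrom="chr1",
            start=1000,
            end=3000,
            strand="+",
            exons=[(1000, 1400), (2600, 3000)],
            utr5=[(1000, 1100)],
            utr3=[(2900, 3000)],
            coding=True,
        ),
        GeneModel(
            gene_id="NC1",
            chrom="chr1",
            start=5000,
            end=6000,
            strand="-",
            exons=[(5000, 5200)],
            coding=False,
        ),
        GeneModel(gene_id="G2", chrom="chr2", start=100, end=900, strand="-",
                  exons=[(100, 900)], coding=True),
    ]


def make_variant(chrom="chr1", pos=1, ref="A", alt="C", rsid="rsX") -> Variant:
    return Variant(rsid=rsid, chrom=chrom, pos=pos, ref=ref, alt=alt)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
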