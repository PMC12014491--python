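"""Shared fixtures: a small simulated dataset and hand-built gene models."""

from __future__ import annotations

import pytest

from bsamap.models import GeneModel, Variant, BulkDepth
from bsamap.simulate import CrossConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> CrossConfig:
    """A desk-sized backcross: 2 × 300-kb chromosomes, 8 genes, 120 variants."""
    return CrossConfig(
        n_chrom=2,
        chrom_len=300_000,
        n_ems=120,
        n_genes=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def make_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    mut: tuple[int, int] = (5, 5),
    wt: tuple[int, int] = (10, 0),
) -> Variant:
    """A two-bulk variant with (ref, alt) read counts per bulk."""
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depths={
            "MUT": BulkDepth(ref_count=mut[0], alt_count=mut[1]),
            "WT": BulkDepth(ref_count=wt[0], alt_count=wt[1]),
        },
    )


# A single-exon + strand gene whose CDS is ATG AGC GCT CAA TAA ("M S A Q *"),
# preceded by 10 A bases; plenty of intergenic space afterwards.
TOY_CDS = "ATGAGCGCTCAATAA"
TOY_GENOME = "A" * 10 + TOY_CDS + "A" * 12_000


@pytest.fixture()
def toy_gene() -> GeneModel:
    return GeneModel(
        gene_id="toy1",
        chrom="chrT",
        strand="+",
        exons=[(11, 25)],
        cds=[(11, 25, 0)],
    )


@pytest.fixture()
def toy_genome() -> dict[str, str]:
    return {"chrT": TOY_GENOME}
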