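"""SNP consequence classification against gene models.

A deliberately small, SNP-only re-implementation of the usual variant
effect classifier: each variant is placed relative to every nearby
transcript (CDS codon, UTR, intron/splice site, 5-kb flanks) and the
most severe consequence wins. Impact tiers follow the SnpEff convention
so that "moderate to high effect" is a well-defined predicate:

====================  ========
effect class          impact
====================  ========
stop_gained           HIGH
stop_lost             HIGH
start_lost            HIGH
splice_site           HIGH
missense              MODERATE
synonymous            LOW
everything else       MODIFIER
====================  ========
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import ConsistencyError
from .models import GeneModel, GenomeSequence, Variant

FLANK_BP = 5_000  # upstream/downstream window
SPLICE_BP = 2  # first/last intronic bases of an intron

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class EffectClass(str, Enum):
    INTERGENIC = "intergenic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    FIVE_PRIME_UTR = "five_prime_UTR"
    THREE_PRIME_UTR = "three_prime_UTR"
    INTRONIC = "intronic"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"


class Impact(str, Enum):
    MODIFIER = "MODIFIER"
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


IMPACT_OF: dict[EffectClass, Impact] = {
    EffectClass.STOP_GAINED: Impact.HIGH,
    EffectClass.STOP_LOST: Impact.HIGH,
    EffectClass.START_LOST: Impact.HIGH,
    EffectClass.SPLICE_SITE: Impact.HIGH,
    EffectClass.MISSENSE: Impact.MODERATE,
    EffectClass.SYNONYMOUS: Impact.LOW,
    EffectClass.INTERGENIC: Impact.MODIFIER,
    EffectClass.UPSTREAM: Impact.MODIFIER,
    EffectClass.DOWNSTREAM: Impact.MODIFIER,
    EffectClass.FIVE_PRIME_UTR: Impact.MODIFIER,
    EffectClass.THREE_PRIME_UTR: Impact.MODIFIER,
    EffectClass.INTRONIC: Impact.MODIFIER,
}

#: most severe first; used to pick the winning transcript annotation
SEVERITY_ORDER = [
    EffectClass.STOP_GAINED,
    EffectClass.STOP_LOST,
    EffectClass.START_LOST,
    EffectClass.SPLICE_SITE,
    EffectClass.MISSENSE,
    EffectClass.SYNONYMOUS,
    EffectClass.FIVE_PRIME_UTR,
    EffectClass.THREE_PRIME_UTR,
    EffectClass.INTRONIC,
    EffectClass.UPSTREAM,
    EffectClass.DOWNSTREAM,
    EffectClass.INTERGENIC,
]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass
class EffectAnnotation:
    """Consequence of one SNP: class, impact, and the codon/aa change if coding."""

    variant: Variant
    gene_id: str | None
    effect_class: EffectClass
    impact: Impact
    codon_change: str | None = None  # e.g. "AGC>AAC", coding strand
    aa_change: str | None = None  # e.g. "S>N"


def genome_index(genome: Iterable[GenomeSequence]) -> dict[str, str]:
    return {g.chrom_id: g.sequence for g in genome}


def cds_positions(model: GeneModel) -> list[int]:
    """1-based genomic positions of the CDS in transcription (5'→3') order."""
    pos: list[int] = []
    for s, e, _ in model.cds:
        pos.extend(range(s, e + 1))
    if model.strand == "-":
        pos.reverse()
    return pos


def extract_cds(model: GeneModel, seq: str) -> str:
    """Coding-strand CDS sequence of a gene model."""
    parts = [seq[s - 1 : e] for s, e, _ in model.cds]
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _coding_effect(
    model: GeneModel, seq: str, variant: Variant
) -> tuple[EffectClass, str, str]:
    """Classify a SNP inside the CDS; returns (class, codon_change, aa_change)."""
    positions = cds_positions(model)
    idx = positions.index(variant.pos)
    codon_i = idx // 3
    offset = idx % 3
    codon_pos = positions[codon_i * 3 : codon_i * 3 + 3]
    ref_codon = "".join(
        seq[p - 1] if model.strand == "+" else _COMP[seq[p - 1]] for p in codon_pos
    )
    alt_base = variant.alt if model.strand == "+" else _COMP[variant.alt]
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        cls = EffectClass.START_LOST
    elif ref_aa == "*" and alt_aa != "*":
        cls = EffectClass.STOP_LOST
    elif ref_aa != "*" and alt_aa == "*":
        cls = EffectClass.STOP_GAINED
    elif ref_aa == alt_aa:
        cls = EffectClass.SYNONYMOUS
    else:
        cls = EffectClass.MISSENSE
    return cls, f"{ref_codon}>{alt_codon}", f"{ref_aa}>{alt_aa}"


def _classify_in_gene(model: GeneModel, seq: str, variant: Variant) -> EffectAnnotation | None:
    """Consequence relative to a single transcript, or None when > 5 kb away."""
    pos = variant.pos
    span_start, span_end = model.span
    if pos < span_start - FLANK_BP or pos > span_end + FLANK_BP:
        return None

    codon_change = aa_change = None
    if pos < span_start or pos > span_end:
        before = pos < span_start
        if (model.strand == "+") == before:
            cls = EffectClass.UPSTREAM
        else:
            cls = EffectClass.DOWNSTREAM
    else:
        in_exon = any(s <= pos <= e for s, e in model.exons)
        in_cds = any(s <= pos <= e for s, e, _ in model.cds)
        if in_cds:
            cls, codon_change, aa_change = _coding_effect(model, seq, variant)
        elif in_exon:
            # UTR: which side of the CDS in transcription order?
            cds_start, cds_end = model.cds[0][0], model.cds[-1][1]
            before_cds = pos < cds_start
            if (model.strand == "+") == before_cds:
                cls = EffectClass.FIVE_PRIME_UTR
            else:
                cls = EffectClass.THREE_PRIME_UTR
        else:
            # intron: splice site = first/last 2 intronic bases
            cls = EffectClass.INTRONIC
            for (s1, e1), (s2, _) in zip(model.exons, model.exons[1:]):
                if e1 < pos < s2:
                    if pos - e1 <= SPLICE_BP or s2 - pos <= SPLICE_BP:
                        cls = EffectClass.SPLICE_SITE
                    break
    return EffectAnnotation(
        variant=variant,
        gene_id=model.gene_id,
        effect_class=cls,
        impact=IMPACT_OF[cls],
        codon_change=codon_change,
        aa_change=aa_change,
    )


def classify_variant(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> EffectAnnotation:
    """Classify one SNP against all gene models.

    When a variant hits several transcripts, the most severe consequence
    wins; ties break toward the lexically lowest gene id. The genome base
    at the variant position must equal the VCF ref allele.
    """
    seq = genome[variant.chrom]
    if seq[variant.pos - 1] != variant.ref:
        raise ConsistencyError(
            f"{variant.chrom}:{variant.pos}: genome base "
            f"{seq[variant.pos - 1]!r} != VCF ref {variant.ref!r}"
        )
    candidates = [
        ann
        for m in gene_models
        if m.chrom == variant.chrom
        for ann in [_classify_in_gene(m, seq, variant)]
        if ann is not None
    ]
    if not candidates:
        return EffectAnnotation(
            variant=variant,
            gene_id=None,
            effect_class=EffectClass.INTERGENIC,
            impact=Impact.MODIFIER,
        )
    return min(candidates, key=lambda a: (_RANK[a.effect_class], a.gene_id))


def annotate_all(
    variants: Sequence[Variant],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[EffectAnnotation]:
    """Order-preserving batch classification; one annotation per variant."""
    out = []
    for i, v in enumerate(variants):
        try:
            out.append(classify_variant(v, gene_models, genome))
        except ConsistencyError as exc:
            raise ConsistencyError(f"variant index {i}: {exc}") from exc
    return out
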