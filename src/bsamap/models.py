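"""Core domain types for bulk-segregant mapping.

Coordinate conventions
----------------------
``Variant.pos`` and ``GeneModel`` intervals are 1-based inclusive, matching
VCF and GFF3. ``Peak`` and ``Window`` intervals are 0-based half-open,
matching BED. Conversions happen exactly once, inside the window / TSS
arithmetic, and are covered by boundary tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

MUT = "MUT"
WT = "WT"
BULKS = (MUT, WT)

VALID_BASES = frozenset("ACGTN")
SNP_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome-scale DNA sequence over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    def validate(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.chrom_id}: empty sequence")
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValidationError(f"{self.chrom_id}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BulkDepth:
    """Per-bulk allele depths at one site."""

    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_frequency(self) -> float:
        """alt / (alt + ref); NaN when the site has no reads."""
        if self.depth == 0:
            return math.nan
        return self.alt_count / self.depth


@dataclass
class Variant:
    """One biallelic site with allele depths for the MUT and WT bulks."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depths: dict[str, BulkDepth] = field(default_factory=dict)
    id: str | None = None

    def validate(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: pos must be >= 1")
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref == alt")
        if set(self.depths) != set(BULKS):
            raise ValidationError(
                f"{self.chrom}:{self.pos}: expected bulks {BULKS}, got "
                f"{sorted(self.depths)}"
            )
        for bulk, d in self.depths.items():
            if d.ref_count < 0 or d.alt_count < 0:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: negative depth in bulk {bulk}"
                )

    @property
    def is_snp(self) -> bool:
        return self.ref in SNP_BASES and self.alt in SNP_BASES

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    """Strand-aware transcript structure.

    ``exons`` and ``cds`` hold 1-based closed intervals sorted by start;
    ``cds`` entries carry the GFF3 phase as a third element. The TSS is the
    strand-aware 5' end of the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """1-based transcription start: leftmost coordinate on +, rightmost on -."""
        return self.span[0] if self.strand == "+" else self.span[1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        for name, ivals in (("exons", self.exons), ("cds", [(s, e) for s, e, _ in self.cds])):
            prev_end = 0
            for s, e in ivals:
                if s < 1 or e < s:
                    raise ValidationError(f"{self.gene_id}: bad {name} interval ({s},{e})")
                if s <= prev_end:
                    raise ValidationError(f"{self.gene_id}: {name} overlap or unsorted at ({s},{e})")
                prev_end = e
        # every CDS interval must lie inside some exon
        for s, e, _ in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS ({s},{e}) outside exons"
                )


@dataclass(frozen=True)
class Peak:
    """A DAP-seq binding peak, 0-based half-open as in BED."""

    chrom: str
    start: int
    end: int
    factor_id: str

    def validate(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"peak {self.factor_id} {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Window:
    """A fixed-width genomic bin summarizing allelic distances.

    ``mean_distance`` and ``sem`` are ``None`` when undefined (no variants,
    or a single variant for the s.e.m.).
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    n_variants: int
    mean_distance: float | None
    sem: float | None


@dataclass(frozen=True)
class MarkerRecord:
    """A PCR mapping marker with its recombinant count among scored mutants."""

    marker_id: str
    chrom: str
    pos_mb: float
    recombinants: int

    def validate(self) -> None:
        if self.recombinants < 0:
            raise ValidationError(f"{self.marker_id}: negative recombinant count")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
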