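"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, VCF through pysam, GFF3 parsing through
gffutils; tables are plain TSV with a header row, read with pandas. All
readers are inverse to the corresponding writers on simulator output.

Bulk identity in two-sample VCFs comes from an explicit sample-name →
{MUT, WT} mapping, never from column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import gffutils

from .errors import ConfigError, FormatError, ValidationError
from .models import (
    BULKS,
    MUT,
    WT,
    BulkDepth,
    GeneModel,
    GenomeSequence,
    MarkerRecord,
    Peak,
    Variant,
)

log = logging.getLogger(__name__)

#: default VCF sample names emitted by the simulator
DEFAULT_SAMPLE_MAP: dict[str, str] = {"MUT_bulk": MUT, "WT_bulk": WT}


# ---------------------------------------------------------------------------
# coordinate conversions (the only place 1-based <-> 0-based happens)
# ---------------------------------------------------------------------------

def to_zero_based(pos_1based: int) -> int:
    """1-based inclusive position -> 0-based offset."""
    return pos_1based - 1


def to_one_based(offset_0based: int) -> int:
    """0-based offset -> 1-based inclusive position."""
    return offset_0based + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into uppercased :class:`GenomeSequence` records."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    if not first.startswith(">"):
        raise FormatError(f"{path}: line 1 is not a FASTA header: {first.strip()!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = GenomeSequence(chrom_id=rec.id, sequence=str(rec.seq).upper())
        seq.validate()
        records.append(seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records (line 1)")
    return records


def write_genome(path: str | Path, sequences: Iterable[GenomeSequence]) -> None:
    recs = [
        SeqRecord(Seq(s.sequence), id=s.chrom_id, description="") for s in sequences
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

class VariantList(list):
    """A list of :class:`Variant` that remembers how many records were skipped."""

    def __init__(self, variants: Iterable[Variant] = (), n_skipped: int = 0):
        super().__init__(variants)
        self.n_skipped = n_skipped


def read_variants(
    path: str | Path,
    sample_map: Mapping[str, str] | None = None,
) -> VariantList:
    """Read biallelic SNPs with per-bulk AD fields from a two-sample VCF.

    Multiallelic records and indels are excluded; the exclusion count is
    logged and exposed as ``result.n_skipped``.

    Parameters
    ----------
    sample_map
        Maps VCF sample name -> bulk label (``"MUT"``/``"WT"``). Defaults to
        the simulator's ``MUT_bulk``/``WT_bulk`` names.
    """
    sample_map = dict(sample_map or DEFAULT_SAMPLE_MAP)
    if sorted(sample_map.values()) != sorted(BULKS):
        raise ConfigError(
            f"sample map must assign exactly the bulks {BULKS}; got {sample_map}"
        )
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    missing = set(sample_map) - set(vcf_samples)
    if missing:
        raise ConfigError(
            f"{path}: samples {sorted(missing)} not in VCF (has {vcf_samples})"
        )
    if "AD" not in vf.header.formats:
        raise FormatError(f"{path}: VCF lacks the FORMAT AD (allele depth) field")

    variants: list[Variant] = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        depths: dict[str, BulkDepth] = {}
        for sample, bulk in sample_map.items():
            ad = rec.samples[sample].get("AD")
            if ad is None or ad[0] is None:
                raise FormatError(
                    f"{path}: missing AD for sample {sample} at "
                    f"{rec.chrom}:{rec.pos}"
                )
            depths[bulk] = BulkDepth(ref_count=int(ad[0]), alt_count=int(ad[1]))
        v = Variant(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=alts[0],
            depths=depths,
            id=None if rec.id in (None, ".") else rec.id,
        )
        v.validate()
        variants.append(v)
    if n_skipped:
        log.info("%s: skipped %d multiallelic/indel records", path, n_skipped)
    return VariantList(variants, n_skipped=n_skipped)


def _vcf_header(
    contig_lengths: Mapping[str, int], samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def write_variants(
    path: str | Path,
    variants: Iterable[Variant],
    contig_lengths: Mapping[str, int],
    sample_map: Mapping[str, str] | None = None,
) -> None:
    """Write bulk variants to an uncompressed two-sample VCF with AD fields."""
    sample_map = dict(sample_map or DEFAULT_SAMPLE_MAP)
    bulk_to_sample = {bulk: sample for sample, bulk in sample_map.items()}
    samples = [bulk_to_sample[MUT], bulk_to_sample[WT]]
    header = _vcf_header(contig_lengths, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                id=v.id,
            )
            for bulk, sample in bulk_to_sample.items():
                d = v.depths[bulk]
                rec.samples[sample]["AD"] = (d.ref_count, d.alt_count)
            out.write(rec)


def read_panel_sites(path: str | Path) -> set[tuple[str, int, str]]:
    """Read an inbred-panel VCF as a simple presence/absence site list.

    Returns ``{(chrom, pos, alt), ...}`` over all ALT alleles.
    """
    vf = pysam.VariantFile(str(path))
    sites: set[tuple[str, int, str]] = set()
    for rec in vf:
        for alt in rec.alts or ():
            sites.add((rec.chrom, rec.pos, alt))
    return sites


def write_panel_sites(
    path: str | Path,
    sites: Iterable[tuple[str, int, str, str]],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write panel sites ``(chrom, pos, ref, alt)`` to a site-only VCF."""
    header = _vcf_header(contig_lengths, samples=[])
    ordered = sorted(sites, key=lambda s: (s[0], s[1], s[3]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, ref, alt in ordered:
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per mRNA."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start, f.end, int(f.frame))
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        model = GeneModel(
            gene_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds=cds,
        )
        try:
            model.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: gene {mrna.id}: {exc}") from exc
        models.append(model)
    return models


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    """Emit gene/mRNA/exon/CDS GFF3 for simulator-generated models."""
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        attrs_gene = f"ID={m.gene_id}_g"
        lines.append(
            "\t".join(
                [m.chrom, "bsamap", "gene", str(start), str(end), ".", m.strand, ".", attrs_gene]
            )
        )
        lines.append(
            "\t".join(
                [
                    m.chrom, "bsamap", "mRNA", str(start), str(end), ".", m.strand, ".",
                    f"ID={m.gene_id};Parent={m.gene_id}_g",
                ]
            )
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                "\t".join(
                    [
                        m.chrom, "bsamap", "exon", str(s), str(e), ".", m.strand, ".",
                        f"ID={m.gene_id}.exon{i};Parent={m.gene_id}",
                    ]
                )
            )
        for i, (s, e, phase) in enumerate(m.cds, 1):
            lines.append(
                "\t".join(
                    [
                        m.chrom, "bsamap", "CDS", str(s), str(e), ".", m.strand, str(phase),
                        f"ID={m.gene_id}.cds{i};Parent={m.gene_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path) -> list[Peak]:
    """Read BED3+1 peaks (column 4 = factor id)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {i}: expected >=4 BED columns")
            peak = Peak(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                factor_id=fields[3],
            )
            peak.validate()
            peaks.append(peak)
    return peaks


def write_peaks(path: str | Path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.factor_id}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        _require_columns(df, required, path)
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression table: ``gene_id`` plus one FPKM column per sample."""
    df = read_table(path, required=["gene_id"])
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression table needs >=1 FPKM column")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential-expression table: gene_id, log2fc, padj [, mean_count]."""
    return read_table(path, required=["gene_id", "log2fc", "padj"])


def read_markers(path: str | Path) -> list[MarkerRecord]:
    df = read_table(path, required=["marker_id", "chrom", "pos_mb", "recombinants"])
    markers = [
        MarkerRecord(
            marker_id=str(r.marker_id),
            chrom=str(r.chrom),
            pos_mb=float(r.pos_mb),
            recombinants=int(r.recombinants),
        )
        for r in df.itertuples()
    ]
    for m in markers:
        m.validate()
    return markers


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
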