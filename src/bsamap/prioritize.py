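"""Ordered filter cascade ranking causal candidates in the mapped interval.

The cascade mirrors the narrative logic of a mutant-mapping study: keep
variants inside the mapped interval, restrict to the EMS mutation
spectrum, require the allele to be specific to the mutant bulk, require a
protein-altering (moderate/high-impact) consequence, drop sites shared
with other inbred backgrounds, and optionally require the affected gene
to be expressed in the relevant tissue. Survivor counts are
non-increasing by construction and the final set is invariant to stage
order and input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError
from .effects import EffectAnnotation, Impact
from .models import Variant
from .scan import AllelicDistanceRecord, Interval

DEFAULT_F_MUT_MIN = 0.25
DEFAULT_F_WT_MAX = 0.05
DEFAULT_FPKM_MIN = 1.0

VariantKey = tuple[str, int, str, str]


def bulk_specific(
    record: AllelicDistanceRecord,
    f_mut_min: float = DEFAULT_F_MUT_MIN,
    f_wt_max: float = DEFAULT_F_WT_MAX,
) -> bool:
    """Whether the alt allele looks private to the mutant bulk."""
    return record.f_mut >= f_mut_min and record.f_wt <= f_wt_max


def expressed_genes(
    expression_table: pd.DataFrame, fpkm_min: float = DEFAULT_FPKM_MIN
) -> set[str]:
    """Genes with FPKM strictly above ``fpkm_min`` in at least one sample."""
    if "gene_id" not in expression_table.columns:
        raise FormatError("expression table lacks a gene_id column")
    value_cols = [c for c in expression_table.columns if c != "gene_id"]
    if not value_cols:
        raise FormatError("expression table has no FPKM columns")
    mask = (expression_table[value_cols] > fpkm_min).any(axis=1)
    return set(expression_table.loc[mask, "gene_id"].astype(str))


@dataclass
class CascadeStage:
    name: str
    description: str
    survivor_count: int
    survivors: list[VariantKey]


@dataclass
class RankedCandidate:
    variant: Variant
    annotation: EffectAnnotation
    distance: float
    gene_expressed: bool | None


@dataclass
class CandidateReport:
    """Per-stage survivor counts plus the final ranked candidate list."""

    stages: list[CascadeStage] = field(default_factory=list)
    final: list[RankedCandidate] = field(default_factory=list)

    def stage_counts(self) -> list[int]:
        return [s.survivor_count for s in self.stages]


def flag_conserved_noncoding(
    annotations: Sequence[EffectAnnotation],
    conserved_regions: Iterable[tuple[str, int, int]],
) -> list[bool]:
    """Flag MODIFIER-impact variants inside conserved non-coding intervals.

    ``conserved_regions`` are BED-style (chrom, start, end), 0-based
    half-open. Coding (or otherwise non-MODIFIER) variants are never
    flagged, whatever their position.
    """
    regions = list(conserved_regions)
    out = []
    for ann in annotations:
        v = ann.variant
        hit = ann.impact == Impact.MODIFIER and any(
            chrom == v.chrom and start <= v.pos - 1 < end
            for chrom, start, end in regions
        )
        out.append(hit)
    return out


_IMPACT_RANK = {Impact.HIGH: 0, Impact.MODERATE: 1, Impact.LOW: 2, Impact.MODIFIER: 3}


def apply_cascade(
    records: Sequence[AllelicDistanceRecord],
    annotations: Sequence[EffectAnnotation],
    interval: Interval | None,
    panel: set[tuple[str, int, str]],
    expressed: set[str] | None = None,
    f_mut_min: float = DEFAULT_F_MUT_MIN,
    f_wt_max: float = DEFAULT_F_WT_MAX,
) -> CandidateReport:
    """Run the ordered filter cascade and rank the survivors.

    Stages, in order: (1) inside the mapped interval; (2) EMS-type;
    (3) bulk-specific (depth-passing with ``f_mut >= f_mut_min`` and
    ``f_wt <= f_wt_max``); (4) impact MODERATE or HIGH; (5) absent from
    the inbred panel; (6, only when ``expressed`` is given) annotated gene
    expressed — variants without a gene are exempt. Ranking: HIGH before
    MODERATE impact, then descending allelic distance, then position.
    """
    ann_by_key: dict[VariantKey, EffectAnnotation] = {}
    for ann in annotations:
        ann_by_key[ann.variant.key] = ann
    missing = [r.variant.key for r in records if r.variant.key not in ann_by_key]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} variants lack annotations (first: {missing[0]})"
        )
    rec_by_key = {r.variant.key: r for r in records}

    def sorted_keys(keys: Iterable[VariantKey]) -> list[VariantKey]:
        return sorted(keys)

    report = CandidateReport()
    current = sorted_keys(rec_by_key)

    def stage(name: str, description: str, keep) -> None:
        nonlocal current
        current = [k for k in current if keep(k)]
        report.stages.append(
            CascadeStage(name, description, len(current), list(current))
        )

    if interval is None:
        stage("interval", "within mapped interval", lambda k: False)
    else:
        stage(
            "interval",
            f"within {interval.chrom}:{interval.start}-{interval.end}",
            lambda k: interval.contains(k[0], k[1]),
        )
    stage("ems_type", "G:C→A:T transition", lambda k: rec_by_key[k].is_ems_type)
    stage(
        "bulk_specific",
        f"depth-passing, f_mut>={f_mut_min}, f_wt<={f_wt_max}",
        lambda k: rec_by_key[k].passes_depth
        and bulk_specific(rec_by_key[k], f_mut_min, f_wt_max),
    )
    stage(
        "impact",
        "MODERATE or HIGH impact",
        lambda k: ann_by_key[k].impact in (Impact.MODERATE, Impact.HIGH),
    )
    stage(
        "panel",
        "absent from inbred panel",
        lambda k: (k[0], k[1], k[3]) not in panel,
    )
    if expressed is not None:
        stage(
            "expressed",
            "annotated gene expressed (FPKM filter); gene-less variants exempt",
            lambda k: ann_by_key[k].gene_id is None
            or ann_by_key[k].gene_id in expressed,
        )

    ranked = sorted(
        current,
        key=lambda k: (
            _IMPACT_RANK[ann_by_key[k].impact],
            -rec_by_key[k].distance,
            k[0],
            k[1],
        ),
    )
    report.final = [
        RankedCandidate(
            variant=rec_by_key[k].variant,
            annotation=ann_by_key[k],
            distance=rec_by_key[k].distance,
            gene_expressed=(
                None
                if expressed is None or ann_by_key[k].gene_id is None
                else ann_by_key[k].gene_id in expressed
            ),
        )
        for k in ranked
    ]
    return report


def report_to_frame(report: CandidateReport) -> pd.DataFrame:
    """Final candidates as a human-readable table."""
    rows = []
    for rank, c in enumerate(report.final, 1):
        rows.append(
            {
                "rank": rank,
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "gene_id": c.annotation.gene_id,
                "effect": c.annotation.effect_class.value,
                "impact": c.annotation.impact.value,
                "aa_change": c.annotation.aa_change,
                "distance": round(c.distance, 4),
                "gene_expressed": c.gene_expressed,
            }
        )
    return pd.DataFrame(rows)
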