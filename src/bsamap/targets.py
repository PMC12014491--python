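"""DAP-seq peak → gene target assignment and DE-overlap arithmetic.

A gene is a putative target of a transcription factor when a binding
peak's midpoint lies within 1 kb (inclusive) of the gene's
transcriptional start site. Shared-target and DE-overlap quantities are
reported as exact rational fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .errors import BsamapError, FormatError
from .models import GeneModel, Peak

DEFAULT_MAX_DIST = 1_000
DEFAULT_PADJ_MAX = 0.05
DEFAULT_LFC_MIN = 0.5


@dataclass(frozen=True)
class TargetAssignment:
    """One (gene, factor, peak) assignment with the signed midpoint–TSS distance.

    The distance is measured on the gene's strand: negative means the
    peak midpoint lies upstream of the TSS.
    """

    gene_id: str
    factor_id: str
    distance: int


def assign_targets(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[TargetAssignment]:
    """Assign peaks to genes whose TSS lies within ``max_dist`` bp (inclusive).

    The peak midpoint is ``floor((start + end) / 2)`` on the 0-based
    half-open peak interval; the 1-based TSS is converted to the same
    frame before differencing.
    """
    out: list[TargetAssignment] = []
    for m in gene_models:
        tss0 = m.tss - 1
        for p in peaks:
            if p.chrom != m.chrom:
                continue
            delta = p.midpoint - tss0
            if m.strand == "-":
                delta = -delta
            if abs(delta) <= max_dist:
                out.append(
                    TargetAssignment(
                        gene_id=m.gene_id, factor_id=p.factor_id, distance=delta
                    )
                )
    return out


def target_sets(assignments: Sequence[TargetAssignment]) -> dict[str, set[str]]:
    """Per-factor sets of target gene ids."""
    sets: dict[str, set[str]] = {}
    for a in assignments:
        sets.setdefault(a.factor_id, set()).add(a.gene_id)
    return sets


@dataclass(frozen=True)
class SharedFractionResult:
    union_size: int
    shared_size: int
    fraction: Fraction | None  # None when the union is empty

    @property
    def value(self) -> float:
        return float(self.fraction) if self.fraction is not None else float("nan")


def shared_fraction(
    sets: Mapping[str, set[str]], shared_min: int = 2
) -> SharedFractionResult:
    """Fraction of the target union bound by at least ``shared_min`` factors."""
    if len(sets) < 2:
        raise BsamapError("shared_fraction requires target sets for >= 2 factors")
    union: set[str] = set().union(*sets.values())
    counts: dict[str, int] = {}
    for genes in sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c >= shared_min}
    frac = Fraction(len(shared), len(union)) if union else None
    return SharedFractionResult(len(union), len(shared), frac)


def filter_de(
    de_table: pd.DataFrame,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    count_min: float | None = None,
) -> tuple[set[str], set[str]]:
    """Split a DE table into (up, down) gene sets with strict thresholds.

    up: ``padj < padj_max`` and ``log2fc > lfc_min``;
    down: ``padj < padj_max`` and ``log2fc < −lfc_min``. When
    ``count_min`` is given, genes with ``mean_count <= count_min`` are
    dropped first.
    """
    for col in ("gene_id", "log2fc", "padj"):
        if col not in de_table.columns:
            raise FormatError(f"DE table lacks required column {col!r}")
    df = de_table
    if count_min is not None:
        if "mean_count" not in df.columns:
            raise FormatError("DE table lacks mean_count but count_min was given")
        df = df[df["mean_count"] > count_min]
    sig = df["padj"] < padj_max
    up = set(df.loc[sig & (df["log2fc"] > lfc_min), "gene_id"].astype(str))
    down = set(df.loc[sig & (df["log2fc"] < -lfc_min), "gene_id"].astype(str))
    return up, down


@dataclass(frozen=True)
class OverlapResult:
    up_fraction: Fraction | None
    down_fraction: Fraction | None


def overlap_targets_de(
    target_union: set[str], up: set[str], down: set[str]
) -> OverlapResult:
    """Fractions of the up/down DE sets that are putative targets.

    An empty DE set yields an undefined (None) fraction rather than a
    division error.
    """
    def frac(de_set: set[str]) -> Fraction | None:
        if not de_set:
            return None
        return Fraction(len(de_set & target_union), len(de_set))

    return OverlapResult(up_fraction=frac(up), down_fraction=frac(down))
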