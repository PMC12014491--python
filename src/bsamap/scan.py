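"""Windowed allelic-distance genome scan for bulk-segregant mapping.

The signal is the *signed* allelic distance ``f_MUT − f_WT`` per variant:
in a backcross segregating a dominant mutation, the expectation is 0.5 at
the causal site (every mutant-bulk individual is a heterozygous carrier,
no normal-bulk individual carries it) and decays toward 0 with map
distance as ``(1 − 2r)/2`` under the Haldane map function. Distances are
averaged in fixed windows (default 0.5 Mbp) and the linked region is the
run of consecutive windows whose mean exceeds a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

import pandas as pd

from .errors import BsamapError
from .models import MUT, WT, MarkerRecord, Variant, Window

DEFAULT_WINDOW_SIZE = 500_000
DEFAULT_MIN_DEPTH = 4
DEFAULT_THRESHOLD = 0.25
DEFAULT_MIN_VARIANTS = 3


@dataclass
class AllelicDistanceRecord:
    """Per-variant bulk allele frequencies and their signed difference."""

    variant: Variant
    f_mut: float
    f_wt: float
    distance: float
    is_ems_type: bool
    passes_depth: bool


def is_ems_type(ref: str, alt: str) -> bool:
    """True iff the substitution is a canonical EMS transition.

    EMS alkylates guanine, producing G:C→A:T transitions; as recorded in a
    VCF this is (ref=G, alt=A) or, on the opposite strand, (ref=C, alt=T).
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise BsamapError(f"is_ems_type requires single-base SNP alleles, got {ref}>{alt}")
    return (ref, alt) in (("G", "A"), ("C", "T"))


def allelic_distance(variant: Variant, min_depth: int = DEFAULT_MIN_DEPTH) -> AllelicDistanceRecord:
    """Compute per-bulk alt frequencies and their difference for one variant.

    Records where either bulk has fewer than ``min_depth`` reads are flagged
    ``passes_depth=False`` and are excluded from window aggregation.
    """
    dm, dw = variant.depths[MUT], variant.depths[WT]
    passes = dm.depth >= min_depth and dw.depth >= min_depth
    f_mut = dm.alt_frequency
    f_wt = dw.alt_frequency
    return AllelicDistanceRecord(
        variant=variant,
        f_mut=f_mut,
        f_wt=f_wt,
        distance=f_mut - f_wt,
        is_ems_type=variant.is_snp and is_ems_type(variant.ref, variant.alt),
        passes_depth=passes,
    )


def compute_records(
    variants: Iterable[Variant],
    min_depth: int = DEFAULT_MIN_DEPTH,
    ems_only: bool = False,
) -> list[AllelicDistanceRecord]:
    """Allelic-distance records for a variant list, optionally EMS-type only."""
    records = [allelic_distance(v, min_depth) for v in variants]
    if ems_only:
        records = [r for r in records if r.is_ems_type]
    return records


def windowed_scan(
    records: Sequence[AllelicDistanceRecord],
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: dict[str, int] | None = None,
) -> list[Window]:
    """Aggregate passing records into fixed, half-open windows.

    Windows tile each chromosome as ``[k*W, (k+1)*W)`` in 0-based
    coordinates. The mean and s.e.m. (sample s.d. / sqrt(n)) are over
    depth-passing records; s.e.m. is undefined (None) for n < 2. When
    ``chrom_lengths`` is given, empty windows are emitted too.
    """
    if window_size <= 0:
        raise BsamapError("window_size must be positive")
    by_window: dict[tuple[str, int], list[float]] = {}
    for rec in records:
        if not rec.passes_depth:
            continue
        k = (rec.variant.pos - 1) // window_size  # 1-based pos -> 0-based offset
        by_window.setdefault((rec.variant.chrom, k), []).append(rec.distance)

    keys: set[tuple[str, int]] = set(by_window)
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            keys.update((chrom, k) for k in range((length + window_size - 1) // window_size))

    windows = []
    for chrom, k in sorted(keys):
        values = by_window.get((chrom, k), [])
        n = len(values)
        windows.append(
            Window(
                chrom=chrom,
                start=k * window_size,
                end=(k + 1) * window_size,
                n_variants=n,
                mean_distance=mean(values) if n else None,
                sem=stdev(values) / math.sqrt(n) if n >= 2 else None,
            )
        )
    return windows


@dataclass(frozen=True)
class Interval:
    """A candidate linked region, 0-based half-open like its windows."""

    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position falls inside the interval."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


def detect_interval(
    windows: Sequence[Window],
    threshold: float = DEFAULT_THRESHOLD,
    min_variants: int = DEFAULT_MIN_VARIANTS,
) -> Interval | None:
    """Find the linked region as a run of consecutive qualifying windows.

    A window qualifies when ``mean_distance >= threshold`` and
    ``n_variants >= min_variants``. Among maximal runs of adjacent
    qualifying windows, the one with the highest peak mean wins; ties break
    toward the longer run, then the lower coordinate. Returns None when no
    window qualifies.
    """
    runs: list[list[Window]] = []
    current: list[Window] = []
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    for w in ordered:
        ok = (
            w.mean_distance is not None
            and w.mean_distance >= threshold
            and w.n_variants >= min_variants
        )
        adjacent = bool(current) and w.chrom == current[-1].chrom and w.start == current[-1].end
        if ok:
            if adjacent:
                current.append(w)
            else:
                current = [w]
                runs.append(current)
        else:
            current = []
    if not runs:
        return None
    best = max(
        runs,
        key=lambda run: (
            max(w.mean_distance for w in run),
            len(run),
            (-ordered.index(run[0])),
        ),
    )
    return Interval(chrom=best[0].chrom, start=best[0].start, end=best[-1].end)


def refine_interval(markers: Sequence[MarkerRecord]) -> tuple[float | None, float | None] | None:
    """Narrow the mapped region using marker recombinant counts.

    The refined interval is bounded by the nearest markers with
    ``recombinants > 0`` flanking the (longest) block of zero-recombinant
    markers; a bound is None (open) at a chromosome end with no flanking
    marker. Returns None when no marker has zero recombinants.
    """
    ordered = sorted(markers, key=lambda m: m.pos_mb)
    blocks: list[tuple[int, int]] = []  # inclusive index ranges of zero blocks
    i = 0
    while i < len(ordered):
        if ordered[i].recombinants == 0:
            j = i
            while j + 1 < len(ordered) and ordered[j + 1].recombinants == 0:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    if not blocks:
        return None
    # longest zero block; ties toward the lower coordinate
    first, last = max(blocks, key=lambda b: (b[1] - b[0], -b[0]))
    left = ordered[first - 1].pos_mb if first > 0 else None
    right = ordered[last + 1].pos_mb if last + 1 < len(ordered) else None
    return (left, right)


def scan_to_frame(windows: Sequence[Window]) -> pd.DataFrame:
    """Windows as a TSV-ready table: chrom, start, end, n, mean, sem."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n": [w.n_variants for w in windows],
            "mean": [w.mean_distance for w in windows],
            "sem": [w.sem for w in windows],
        }
    )
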