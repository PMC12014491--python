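"""Truth-annotated synthetic data for an EMS backcross mapping experiment.

The generator emulates the study design the scan assumes: a dominant
EMS-induced mutation segregating in a backcross (mutant/+ × +/+), with
phenotype-selected bulks of 80 individuals pooled and sequenced at ~10×
coverage per bulk. Induced variants follow the canonical EMS spectrum
(99% G:C→A:T transitions by default) and are heterozygous in the
mutagenized parent, in coupling with the causal site. Co-segregation
follows the Haldane map function and pooled read counts follow
Poisson depth with binomial allele sampling plus a per-read miscall rate.

Every generated dataset carries a :class:`SimTruth` record sufficient to
score every downstream stage without re-simulation, and identical
config + seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .errors import ConfigError, PlacementError, SizingError
from .models import MUT, WT, BulkDepth, GeneModel, GenomeSequence, Peak, Variant, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

from Bio.Seq import Seq as _Seq

_CODON_TABLE = {c: str(_Seq(c).translate()) for c in _SENSE_CODONS + _STOPS}


@dataclass
class CrossConfig:
    """Study-design parameters for the simulated backcross.

    Defaults are the experiment's stated design where one exists (bulks of
    80 individuals, 10× sequencing coverage, an overwhelmingly G:C→A:T
    EMS spectrum) and field-standard choices elsewhere (Haldane map at
    1 cM/Mbp, Poisson depth, 0.1% per-read miscall).
    """

    n_chrom: int = 3
    chrom_len: int = 10_000_000
    n_bulk: int = 80
    coverage: float = 10.0
    n_ems: int = 1_500
    ems_transition_fraction: float = 0.99
    cm_per_mb: float = 1.0
    error_rate: float = 0.001
    panel_fraction: float = 0.10
    n_genes: int = 40
    misphenotyping_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_len", "n_bulk", "n_ems", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "ems_transition_fraction",
            "panel_fraction",
            "misphenotyping_rate",
            "error_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ConfigError("coverage must be positive")


def haldane_r(morgans: float) -> float:
    """Recombination fraction at a map distance (Haldane, no interference)."""
    return 0.5 * (1.0 - math.exp(-2.0 * morgans))


def map_distance_morgans(delta_bp: int, cm_per_mb: float) -> float:
    """Physical separation to map distance: |Δbp| × (cM/Mbp) × 10⁻⁸ Morgans/bp·cM."""
    return abs(delta_bp) * cm_per_mb * 1e-8


def expected_allelic_distance(morgans: float) -> float:
    """Closed-form E[f_MUT − f_WT] at a map distance: (1 − 2r)/2."""
    return (1.0 - 2.0 * haldane_r(morgans)) / 2.0


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    is_ems_transition: bool
    in_panel: bool
    r_to_causal: float
    is_causal: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        if self.in_panel:
            return "panel_shared"
        return "ems_transition" if self.is_ems_transition else "other"


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal: tuple[str, int, str, str]
    causal_gene: str
    causal_effect: str
    variants: list[VariantTruth]
    expressed_genes: list[str] = field(default_factory=list)
    target_truth: list[dict] = field(default_factory=list)  # planted peak offsets
    seed: int = 0

    def by_key(self) -> dict[tuple[str, int, str, str], VariantTruth]:
        return {vt.key: vt for vt in self.variants}

    def to_json(self) -> str:
        payload = {
            "schema": "bsamap-truth-v1",
            "causal": list(self.causal),
            "causal_gene": self.causal_gene,
            "causal_effect": self.causal_effect,
            "seed": self.seed,
            "expressed_genes": sorted(self.expressed_genes),
            "target_truth": self.target_truth,
            "variants": [asdict(vt) for vt in self.variants],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            causal=tuple(d["causal"]),
            causal_gene=d["causal_gene"],
            causal_effect=d["causal_effect"],
            variants=[VariantTruth(**vt) for vt in d["variants"]],
            expressed_genes=list(d.get("expressed_genes", [])),
            target_truth=list(d.get("target_truth", [])),
            seed=d.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def simulate_genome(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> list[GenomeSequence]:
    """I.i.d.-uniform random chromosomes, deterministic given the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_chrom):
        draws = rng.integers(0, 4, size=config.chrom_len)
        seq = _BASES[draws].tobytes().decode("ascii")
        out.append(GenomeSequence(chrom_id=f"chr{i + 1}", sequence=seq))
    return out


def _build_gene(
    rng: np.random.Generator,
    chrom: str,
    slot_start: int,
    slot_end: int,
    gene_id: str,
) -> GeneModel:
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(120, 301, size=n_exons)
    intron_lens = rng.integers(80, 201, size=n_exons - 1)
    gene_len = int(exon_lens.sum() + intron_lens.sum())
    margin = 1_000
    lo, hi = slot_start + margin, slot_end - margin - gene_len
    if hi <= lo:
        raise SizingError(
            f"{gene_id}: gene of {gene_len} bp does not fit slot "
            f"[{slot_start}, {slot_end}) with {margin} bp margins"
        )
    start = int(rng.integers(lo, hi))
    strand = "+" if rng.random() < 0.5 else "-"

    exons: list[tuple[int, int]] = []
    p = start
    for i in range(n_exons):
        exons.append((p, p + int(exon_lens[i]) - 1))
        p += int(exon_lens[i])
        if i < n_exons - 1:
            p += int(intron_lens[i])

    # transcript offsets in transcription order; trim UTRs and enforce CDS % 3
    tx_positions: list[int] = []
    for s, e in exons:
        tx_positions.extend(range(s, e + 1))
    if strand == "-":
        tx_positions.reverse()
    utr5 = utr3 = 30
    cds_tx = tx_positions[utr5 : len(tx_positions) - utr3]
    cds_tx = cds_tx[: len(cds_tx) - (len(cds_tx) % 3)]
    cds_sorted = sorted(cds_tx)

    # group into genomic intervals, then attach phases in transcription order
    intervals: list[tuple[int, int]] = []
    run_start = prev = cds_sorted[0]
    for q in cds_sorted[1:]:
        if q == prev + 1:
            prev = q
            continue
        intervals.append((run_start, prev))
        run_start = prev = q
    intervals.append((run_start, prev))

    tx_order = intervals if strand == "+" else list(reversed(intervals))
    phases: dict[tuple[int, int], int] = {}
    cum = 0
    for s, e in tx_order:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s + 1
    cds = [(s, e, phases[(s, e)]) for s, e in intervals]

    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, cds=cds)


def simulate_gene_models(
    genome: list[GenomeSequence],
    n_genes: int,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], list[GenomeSequence]]:
    """Place non-overlapping multi-exon genes and write valid CDS into the genome.

    Each concatenated CDS begins with ATG, ends with a stop codon, has length
    divisible by 3, and contains no internal stop. Returns the models and the
    edited genome.
    """
    per_chrom = [n_genes // len(genome)] * len(genome)
    for i in range(n_genes % len(genome)):
        per_chrom[i] += 1
    models: list[GeneModel] = []
    edited: list[GenomeSequence] = []
    gene_no = 0
    for chrom_seq, n_here in zip(genome, per_chrom):
        buf = bytearray(chrom_seq.sequence, "ascii")
        if n_here:
            slot = len(buf) // n_here
            for k in range(n_here):
                gene_no += 1
                model = _build_gene(
                    rng,
                    chrom_seq.chrom_id,
                    slot * k,
                    slot * (k + 1),
                    f"gene{gene_no:04d}",
                )
                _write_cds(buf, model, rng)
                models.append(model)
        edited.append(
            GenomeSequence(chrom_id=chrom_seq.chrom_id, sequence=buf.decode("ascii"))
        )
    return models, edited


def _write_cds(buf: bytearray, model: GeneModel, rng: np.random.Generator) -> None:
    positions = []  # transcription order
    for s, e, _ in model.cds:
        positions.extend(range(s, e + 1))
    if model.strand == "-":
        positions.reverse()
    n_codons = len(positions) // 3
    codons = ["ATG"]
    codons += [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)]
    codons.append(_STOPS[rng.integers(0, 3)])
    coding = "".join(codons)
    for base, pos in zip(coding, positions):
        b = base if model.strand == "+" else _COMP[base]
        buf[pos - 1] = ord(b)


# ---------------------------------------------------------------------------
# EMS variants
# ---------------------------------------------------------------------------

def _causal_candidates(
    model: GeneModel, seq: str
) -> list[tuple[int, str, str, str]]:
    """(pos, ref, alt, effect) for EMS transitions in the CDS that change protein."""
    positions = []
    for s, e, _ in model.cds:
        positions.extend(range(s, e + 1))
    if model.strand == "-":
        positions.reverse()
    coding = "".join(
        seq[p - 1] if model.strand == "+" else _COMP[seq[p - 1]] for p in positions
    )
    out = []
    for i, base in enumerate(coding):
        if base not in "GC":
            continue
        codon_i, offset = divmod(i, 3)
        if codon_i == 0 or codon_i >= len(coding) // 3 - 1:
            continue  # keep start and stop codons intact
        ref_codon = coding[codon_i * 3 : codon_i * 3 + 3]
        alt_base = "A" if base == "G" else "T"
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        ref_aa, alt_aa = _CODON_TABLE[ref_codon], _CODON_TABLE[alt_codon]
        if ref_aa == alt_aa:
            continue
        effect = "stop_gained" if alt_aa == "*" else "missense"
        pos = positions[i]
        g_ref = seq[pos - 1]
        g_alt = "A" if g_ref == "G" else "T"
        out.append((pos, g_ref, g_alt, effect))
    return out


def simulate_ems_variants(
    genome: list[GenomeSequence],
    gene_models: Sequence[GeneModel],
    config: CrossConfig,
    rng: np.random.Generator,
) -> tuple[list[Variant], SimTruth]:
    """Place the EMS variant set, including exactly one protein-altering causal.

    A fraction ``ems_transition_fraction`` of variants are G→A or C→T at
    G/C reference sites; the rest are non-EMS substitutions. The causal
    variant is an EMS transition inside a CDS producing a missense (or, if
    none is available, stop-gain) change. A ``panel_fraction`` subset of
    non-causal variants is flagged as shared with other inbred backgrounds.
    Returned variants carry no depths yet (see :func:`simulate_bulks`).
    """
    seqs = {g.chrom_id: g.sequence for g in genome}
    lengths = {g.chrom_id: len(g.sequence) for g in genome}

    causal_gene = gene_models[rng.integers(0, len(gene_models))]
    candidates = _causal_candidates(causal_gene, seqs[causal_gene.chrom])
    missense = [c for c in candidates if c[3] == "missense"]
    pool = missense or candidates
    if not pool:
        raise PlacementError(
            f"no eligible protein-altering EMS site in CDS of {causal_gene.gene_id}"
        )
    pos, ref, alt, effect = pool[rng.integers(0, len(pool))]
    causal = VariantTruth(
        chrom=causal_gene.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        is_ems_transition=True,
        in_panel=False,
        r_to_causal=0.0,
        is_causal=True,
    )

    chroms = [g.chrom_id for g in genome]
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    taken = {(causal.chrom, causal.pos)}
    truths = [causal]
    n_other = config.n_ems - 1
    want_transition = rng.random(n_other) < config.ems_transition_fraction
    in_panel = rng.random(n_other) < config.panel_fraction
    for i in range(n_other):
        while True:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            p = int(rng.integers(1, lengths[chrom] + 1))
            if (chrom, p) in taken:
                continue
            base = seqs[chrom][p - 1]
            if want_transition[i]:
                if base not in "GC":
                    continue
                v_ref, v_alt = base, ("A" if base == "G" else "T")
            else:
                if base == "N":
                    continue
                options = [b for b in "ACGT" if b != base]
                if base == "G":
                    options.remove("A")
                elif base == "C":
                    options.remove("T")
                v_alt = options[rng.integers(0, len(options))]
                v_ref = base
            break
        taken.add((chrom, p))
        if chrom == causal.chrom:
            r = haldane_r(map_distance_morgans(p - causal.pos, config.cm_per_mb))
        else:
            r = 0.5
        truths.append(
            VariantTruth(
                chrom=chrom,
                pos=p,
                ref=v_ref,
                alt=v_alt,
                is_ems_transition=bool(want_transition[i]),
                in_panel=bool(in_panel[i]),
                r_to_causal=r,
                is_causal=False,
            )
        )

    truths.sort(key=lambda t: (t.chrom, t.pos))
    variants = [
        Variant(chrom=t.chrom, pos=t.pos, ref=t.ref, alt=t.alt) for t in truths
    ]
    truth = SimTruth(
        causal=causal.key,
        causal_gene=causal_gene.gene_id,
        causal_effect=effect,
        variants=truths,
        seed=config.seed,
    )
    return variants, truth


# ---------------------------------------------------------------------------
# pooled bulk sequencing
# ---------------------------------------------------------------------------

def simulate_bulks(
    variants: Sequence[Variant],
    truth: SimTruth,
    config: CrossConfig,
    rng: np.random.Generator,
) -> list[Variant]:
    """Draw pooled read depths for the MUT and WT bulks at every variant.

    Backcross model: every MUT-bulk individual carries the causal
    chromatid; a same-chromosome variant at recombination fraction r rides
    along with probability 1−r (probability r in the WT bulk); variants on
    other chromosomes segregate independently (probability ½ in both
    bulks). Carriers are heterozygous, so the pooled alt frequency is
    carriers/(2·n_bulk). Site depth is Poisson(coverage) per bulk and alt
    reads are Binomial(depth, f·(1−e) + (1−f)·e) with miscall rate e.
    """
    tmap = truth.by_key()
    causal_chrom = truth.causal[0]
    n = config.n_bulk
    pm = config.misphenotyping_rate
    out = []
    for v in variants:
        t = tmap[v.key]
        if v.chrom == causal_chrom:
            r = t.r_to_causal
            p_mut = (1 - pm) * (1 - r) + pm * r
            p_wt = (1 - pm) * r + pm * (1 - r)
        else:
            p_mut = p_wt = 0.5
        depths = {}
        for bulk, p_carry in ((MUT, p_mut), (WT, p_wt)):
            carriers = rng.binomial(n, p_carry)
            f = carriers / (2 * n)
            f_obs = f * (1 - config.error_rate) + (1 - f) * config.error_rate
            depth = rng.poisson(config.coverage)
            alt = rng.binomial(depth, f_obs) if depth else 0
            depths[bulk] = BulkDepth(ref_count=int(depth - alt), alt_count=int(alt))
        out.append(
            Variant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, depths=depths)
        )
    return out


# ---------------------------------------------------------------------------
# downstream fixtures: expression, peaks, qPCR, decay, DE
# ---------------------------------------------------------------------------

def _gene_ids(gene_models: Iterable) -> list[str]:
    return [m.gene_id if hasattr(m, "gene_id") else str(m) for m in gene_models]


def simulate_expression(
    gene_models: Sequence,
    rng: np.random.Generator,
    expressed_fraction: float = 0.625,
    n_samples: int = 2,
    always_expressed: Iterable[str] = (),
) -> tuple[pd.DataFrame, set[str]]:
    """Log-normal FPKM table with a configured fraction of genes above 1 FPKM.

    The default expressed fraction mirrors the mapped interval's 5-of-8
    expressed genes. ``always_expressed`` genes (the causal gene: the
    mutant phenotype presupposes it acts in the sampled tissue) are forced
    above 1 FPKM. Returns the table and the truth set of expressed genes.
    """
    ids = _gene_ids(gene_models)
    forced = set(always_expressed)
    expressed = (rng.random(len(ids)) < expressed_fraction) | np.array(
        [g in forced for g in ids]
    )
    base = np.where(
        expressed,
        1.1 + rng.lognormal(mean=1.0, sigma=1.0, size=len(ids)),
        rng.uniform(0.0, 0.8, size=len(ids)),
    )
    data = {"gene_id": ids}
    for s in range(n_samples):
        vals = base * np.exp(rng.normal(0.0, 0.02, size=len(ids)))
        vals = np.where(expressed, np.maximum(vals, 1.01), np.minimum(vals, 0.99))
        data[f"fpkm_{s + 1}"] = np.round(vals, 4)
    df = pd.DataFrame(data)
    return df, {g for g, e in zip(ids, expressed) if e}


def simulate_peaks(
    gene_models: Sequence[GeneModel],
    factors: Sequence[str],
    rng: np.random.Generator,
    target_prob: float = 0.5,
    max_true_offset: int = 800,
    decoy_prob: float = 0.3,
    decoy_offset_range: tuple[int, int] = (1_500, 5_000),
    peak_halfwidth: int = 100,
) -> tuple[list[Peak], list[dict]]:
    """Plant DAP-seq peaks at known TSS offsets.

    True targets get a peak whose midpoint is within ``max_true_offset`` bp
    of the TSS (signed along the gene's strand); decoys sit beyond 1 kb of
    *every* TSS on the chromosome, so the planted truth coincides exactly
    with the 1-kb assignment rule. Returns the peaks and a truth list of
    planted (gene, factor, offset).
    """
    tss_by_chrom: dict[str, list[int]] = {}
    for m in gene_models:
        tss_by_chrom.setdefault(m.chrom, []).append(m.tss - 1)

    peaks: list[Peak] = []
    planted: list[dict] = []
    for factor in factors:
        for m in gene_models:
            u = rng.random()
            tss0 = m.tss - 1
            if u < target_prob:
                offset = int(rng.integers(-max_true_offset, max_true_offset + 1))
                mid = tss0 + offset if m.strand == "+" else tss0 - offset
            elif u < target_prob + decoy_prob:
                mid = None
                for _ in range(20):  # resample until clear of all TSSs
                    sign = 1 if rng.random() < 0.5 else -1
                    offset = sign * int(rng.integers(*decoy_offset_range))
                    cand = tss0 + offset if m.strand == "+" else tss0 - offset
                    if all(abs(cand - t) > 1_000 for t in tss_by_chrom[m.chrom]):
                        mid = cand
                        break
                if mid is None:
                    continue
            else:
                continue
            if mid < peak_halfwidth:
                continue  # clipping would move the midpoint off the planted offset
            peaks.append(
                Peak(
                    chrom=m.chrom,
                    start=mid - peak_halfwidth,
                    end=mid + peak_halfwidth,
                    factor_id=factor,
                )
            )
            planted.append(
                {
                    "gene_id": m.gene_id,
                    "factor_id": factor,
                    "offset": offset,
                    "is_target": abs(offset) <= 1_000,
                }
            )
    return peaks, planted


def simulate_ct_table(
    rng: np.random.Generator,
    target_gene: str = "target",
    ref_gene: str = "reference",
    group_log2_rq: dict[str, float] | None = None,
    calibrator_group: str = "mock_WT",
    n_per_group: int = 3,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """qPCR Ct table with known relative quantities per sample group.

    ``group_log2_rq`` maps group name -> true log2 relative quantity versus
    the calibrator group (which is always included at 0).
    """
    groups = {calibrator_group: 0.0}
    groups.update(group_log2_rq or {"treated_mut": 2.0})
    rows = []
    truth = {}
    for group, l2 in groups.items():
        for i in range(1, n_per_group + 1):
            sample = f"{group}_{i}"
            truth[sample] = 2.0 ** l2
            ref_ct = 20.0 + rng.normal(0.0, 0.3)
            dct = 3.0 - l2  # ΔCt shifts down one cycle per doubling
            for _ in range(n_replicates):
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": ref_gene,
                        "ct": round(ref_ct + rng.normal(0.0, noise_sd), 4),
                    }
                )
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": target_gene,
                        "ct": round(ref_ct + dct + rng.normal(0.0, noise_sd), 4),
                    }
                )
    return pd.DataFrame(rows), truth


def simulate_decay_series(
    rng: np.random.Generator,
    half_life: float = 4.0,
    s0: float = 1.0,
    timepoints: Sequence[float] = (0.0, 2.0, 4.0, 8.0),
    noise: float = 0.05,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Exponential-decay series S(t) = S0·2^(−t/τ) with multiplicative noise."""
    rows = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            signal = s0 * 2.0 ** (-t / half_life)
            if noise > 0:
                signal *= math.exp(rng.normal(0.0, noise))
            rows.append({"replicate": rep, "time_h": t, "signal": signal})
    return pd.DataFrame(rows)


def simulate_de_table(
    gene_models: Sequence,
    rng: np.random.Generator,
    frac_up: float = 0.1,
    frac_down: float = 0.1,
) -> pd.DataFrame:
    """DE results with known up/down membership at the standard thresholds."""
    ids = _gene_ids(gene_models)
    u = rng.random(len(ids))
    rows = []
    for gid, x in zip(ids, u):
        if x < frac_up:
            lfc = 0.5 + rng.exponential(1.0)
            padj = rng.uniform(1e-6, 0.049)
        elif x < frac_up + frac_down:
            lfc = -0.5 - rng.exponential(1.0)
            padj = rng.uniform(1e-6, 0.049)
        else:
            lfc = rng.normal(0.0, 0.2)
            padj = rng.uniform(0.05, 1.0)
        rows.append(
            {
                "gene_id": gid,
                "log2fc": round(float(lfc), 4),
                "padj": round(float(padj), 6),
                "mean_count": round(float(rng.lognormal(4.0, 1.0)), 2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """All inputs of one simulated experiment plus its ground truth."""

    config: CrossConfig
    genome: list[GenomeSequence]
    gene_models: list[GeneModel]
    bulk_variants: list[Variant]
    panel_sites: set[tuple[str, int, str]]
    expression: pd.DataFrame
    peaks: list[Peak]
    de_table: pd.DataFrame
    truth: SimTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {g.chrom_id: len(g.sequence) for g in self.genome}


def simulate_dataset(
    config: CrossConfig,
    factors: Sequence[str] = ("factorA", "factorB", "factorC"),
) -> SimulatedDataset:
    """Generate a complete, internally consistent dataset from one config."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    gene_models, genome = simulate_gene_models(genome, config.n_genes, rng)
    templates, truth = simulate_ems_variants(genome, gene_models, config, rng)
    bulk_variants = simulate_bulks(templates, truth, config, rng)
    panel_sites = {
        (t.chrom, t.pos, t.alt) for t in truth.variants if t.in_panel
    }
    expression, expressed = simulate_expression(
        gene_models, rng, always_expressed={truth.causal_gene}
    )
    truth.expressed_genes = sorted(expressed)
    peaks, planted = simulate_peaks(gene_models, factors, rng)
    truth.target_truth = planted
    de_table = simulate_de_table(gene_models, rng)
    return SimulatedDataset(
        config=config,
        genome=genome,
        gene_models=gene_models,
        bulk_variants=bulk_variants,
        panel_sites=panel_sites,
        expression=expression,
        peaks=peaks,
        de_table=de_table,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset as standard-format files plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "bulks": outdir / "bulks.vcf",
        "panel": outdir / "panel.vcf",
        "expression": outdir / "expression.tsv",
        "peaks": outdir / "peaks.bed",
        "de": outdir / "de.tsv",
        "truth": outdir / "truth.json",
    }
    gio.write_genome(paths["genome"], dataset.genome)
    gio.write_gene_models(paths["genes"], dataset.gene_models)
    gio.write_variants(paths["bulks"], dataset.bulk_variants, dataset.contig_lengths)
    panel_rows = [
        (t.chrom, t.pos, t.ref, t.alt) for t in dataset.truth.variants if t.in_panel
    ]
    gio.write_panel_sites(paths["panel"], panel_rows, dataset.contig_lengths)
    gio.write_table(paths["expression"], dataset.expression)
    gio.write_peaks(paths["peaks"], dataset.peaks)
    gio.write_table(paths["de"], dataset.de_table)
    paths["truth"].write_text(dataset.truth.to_json())
    return paths
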