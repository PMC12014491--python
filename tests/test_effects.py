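"""Consequence classification: codon cases, gene anatomy, oracle equivalence."""

import numpy as np
import pytest
from Bio.Seq import Seq

from bsamap.effects import (
    EffectClass,
    Impact,
    annotate_all,
    classify_variant,
    extract_cds,
)
from bsamap.errors import ConsistencyError
from bsamap.models import GeneModel, Variant, revcomp

from conftest import TOY_GENOME, make_variant


def classify(genome, models, chrom, pos, ref, alt):
    v = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
    return classify_variant(v, models, genome)


class TestCodonCases:
    """TOY gene: CDS = ATG AGC GCT CAA TAA at chrT:11-25 (+)."""

    def test_missense_ser_to_asn(self, toy_gene, toy_genome):
        # G->A at the middle of AGC gives AAC: Ser -> Asn, MODERATE
        ann = classify(toy_genome, [toy_gene], "chrT", 15, "G", "A")
        assert ann.effect_class == EffectClass.MISSENSE
        assert ann.impact == Impact.MODERATE
        assert ann.codon_change == "AGC>AAC"
        assert ann.aa_change == "S>N"

    def test_stop_gained(self, toy_gene, toy_genome):
        # C->T at the first base of CAA gives TAA: stop gained, HIGH
        ann = classify(toy_genome, [toy_gene], "chrT", 20, "C", "T")
        assert ann.effect_class == EffectClass.STOP_GAINED
        assert ann.impact == Impact.HIGH

    def test_synonymous_third_position(self, toy_gene, toy_genome):
        # T->A at the third base of GCT gives GCA: Ala -> Ala, LOW
        ann = classify(toy_genome, [toy_gene], "chrT", 19, "T", "A")
        assert ann.effect_class == EffectClass.SYNONYMOUS
        assert ann.impact == Impact.LOW
        assert ann.aa_change == "A>A"

    def test_start_lost(self, toy_gene, toy_genome):
        ann = classify(toy_genome, [toy_gene], "chrT", 11, "A", "G")
        assert ann.effect_class == EffectClass.START_LOST
        assert ann.impact == Impact.HIGH

    def test_stop_lost(self, toy_gene, toy_genome):
        ann = classify(toy_genome, [toy_gene], "chrT", 23, "T", "C")
        assert ann.effect_class == EffectClass.STOP_LOST
        assert ann.impact == Impact.HIGH

    def test_intergenic_beyond_flank(self, toy_gene, toy_genome):
        ann = classify(toy_genome, [toy_gene], "chrT", 25 + 5_001, "A", "G")
        assert ann.effect_class == EffectClass.INTERGENIC
        assert ann.gene_id is None

    def test_upstream_downstream_within_flank(self, toy_gene, toy_genome):
        up = classify(toy_genome, [toy_gene], "chrT", 5, "A", "G")
        down = classify(toy_genome, [toy_gene], "chrT", 30, "A", "G")
        assert up.effect_class == EffectClass.UPSTREAM
        assert down.effect_class == EffectClass.DOWNSTREAM

    def test_genome_ref_mismatch_is_consistency_error(self, toy_gene, toy_genome):
        with pytest.raises(ConsistencyError, match="chrT:15"):
            classify(toy_genome, [toy_gene], "chrT", 15, "C", "A")


TWO_EXON_CDS = "ATGAGCGCTCAAAAACCCGGGTTTACGTAA"  # 10 codons


def _two_exon_gene():
    # exon1 chrT2:11-25, intron 26-105, exon2 106-120; CDS covers both exons
    genome = "A" * 10 + TWO_EXON_CDS[:15] + "G" * 80 + TWO_EXON_CDS[15:] + "A" * 6_000
    model = GeneModel("g2", "chrT2", "+", exons=[(11, 25), (106, 120)],
                      cds=[(11, 25, 0), (106, 120, 0)])
    return model, {"chrT2": genome}


class TestGeneAnatomy:
    def test_splice_site_first_two_intron_bases(self):
        model, genome = _two_exon_gene()
        for pos in (26, 27, 104, 105):
            ann = classify(genome, [model], "chrT2", pos, "G", "A")
            assert ann.effect_class == EffectClass.SPLICE_SITE, pos
            assert ann.impact == Impact.HIGH
        for pos in (28, 103):
            ann = classify(genome, [model], "chrT2", pos, "G", "A")
            assert ann.effect_class == EffectClass.INTRONIC

    def test_utr_classification_is_strand_aware(self):
        # add UTR exon space around the CDS on a plus-strand gene
        genome = {"chrU": "A" * 10 + "TTTTT" + "ATGGCTTAA" + "CCCCC" + "A" * 6_000}
        model = GeneModel(
            "gU", "chrU", "+", exons=[(11, 29)], cds=[(16, 24, 0)]
        )
        five = classify(genome, [model], "chrU", 12, "T", "A")
        three = classify(genome, [model], "chrU", 27, "C", "A")
        assert five.effect_class == EffectClass.FIVE_PRIME_UTR
        assert three.effect_class == EffectClass.THREE_PRIME_UTR
        minus = GeneModel(
            "gU", "chrU", "-", exons=[(11, 29)], cds=[(16, 24, 0)]
        )
        genome_m = {"chrU": "A" * 10 + "TTTTT" + "TTAAGCCAT" + "CCCCC" + "A" * 6_000}
        assert (
            classify(genome_m, [minus], "chrU", 12, "T", "A").effect_class
            == EffectClass.THREE_PRIME_UTR
        )
        assert (
            classify(genome_m, [minus], "chrU", 27, "C", "A").effect_class
            == EffectClass.FIVE_PRIME_UTR
        )

    def test_most_severe_transcript_wins_with_gene_id_tiebreak(self, toy_genome, toy_gene):
        # a second transcript whose CDS excludes position 15 -> UTR there
        other = GeneModel("toy0", "chrT", "+", exons=[(11, 25)], cds=[(17, 25, 0)])
        ann = classify(toy_genome, [toy_gene, other], "chrT", 15, "G", "A")
        assert ann.gene_id == "toy1" and ann.effect_class == EffectClass.MISSENSE
        # identical class in both -> lexically lowest gene id
        twin = GeneModel("toy0", "chrT", "+", exons=[(11, 25)], cds=[(11, 25, 0)])
        ann = classify(toy_genome, [toy_gene, twin], "chrT", 15, "G", "A")
        assert ann.gene_id == "toy0"


def translation_oracle(model, seq, variant):
    """Independent full-CDS translate-and-diff classification."""
    ref_cds = extract_cds(model, seq)
    mutated = seq[: variant.pos - 1] + variant.alt + seq[variant.pos :]
    alt_cds = extract_cds(model, mutated)
    if ref_cds[:3] == "ATG" and alt_cds[:3] != "ATG":
        return EffectClass.START_LOST
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    if ref_prot == alt_prot:
        return EffectClass.SYNONYMOUS
    (i,) = [k for k in range(len(ref_prot)) if ref_prot[k] != alt_prot[k]]
    if ref_prot[i] == "*":
        return EffectClass.STOP_LOST
    if alt_prot[i] == "*":
        return EffectClass.STOP_GAINED
    return EffectClass.MISSENSE


def random_cds_snps(dataset, n, seed):
    """Random SNPs inside simulated CDS regions, with matching gene model."""
    rng = np.random.default_rng(seed)
    seqs = {g.chrom_id: g.sequence for g in dataset.genome}
    out = []
    models = dataset.gene_models
    while len(out) < n:
        m = models[rng.integers(0, len(models))]
        s, e, _ = m.cds[rng.integers(0, len(m.cds))]
        pos = int(rng.integers(s, e + 1))
        ref = seqs[m.chrom][pos - 1]
        alt = "ACGT"[rng.integers(0, 4)]
        if alt == ref:
            continue
        out.append((m, Variant(chrom=m.chrom, pos=pos, ref=ref, alt=alt)))
    return out, seqs


class TestOracleEquivalence:
    def test_classifier_matches_translation_oracle_on_500_snps(self, small_dataset):
        snps, seqs = random_cds_snps(small_dataset, 500, seed=123)
        for model, v in snps:
            ann = classify_variant(v, [model], seqs)
            assert ann.effect_class == translation_oracle(model, seqs[v.chrom], v), (
                model.gene_id,
                v,
            )

    def test_strand_mirroring_preserves_class_and_aa_change(self, small_dataset):
        snps, seqs = random_cds_snps(small_dataset, 60, seed=7)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for model, v in snps:
            L = len(seqs[v.chrom])
            flip = lambda p: L - p + 1
            mirrored_seq = {v.chrom: revcomp(seqs[v.chrom])}
            mirrored_model = GeneModel(
                gene_id=model.gene_id,
                chrom=model.chrom,
                strand="-" if model.strand == "+" else "+",
                exons=sorted((flip(e), flip(s)) for s, e in model.exons),
                cds=sorted((flip(e), flip(s), 0) for s, e, _ in model.cds),
            )
            mv = Variant(
                chrom=v.chrom, pos=flip(v.pos), ref=comp[v.ref], alt=comp[v.alt]
            )
            a1 = classify_variant(v, [model], seqs)
            a2 = classify_variant(mv, [mirrored_model], mirrored_seq)
            assert a1.effect_class == a2.effect_class
            assert a1.aa_change == a2.aa_change
            assert a1.codon_change == a2.codon_change


class TestBatch:
    def test_empty_input(self, toy_gene, toy_genome):
        assert annotate_all([], [toy_gene], toy_genome) == []

    def test_batch_equals_per_variant_and_preserves_order(self, toy_gene, toy_genome):
        variants = [
            Variant(chrom="chrT", pos=p, ref=TOY_GENOME[p - 1], alt="A" if TOY_GENOME[p - 1] != "A" else "G")
            for p in (15, 20, 2_000)
        ]
        batch = annotate_all(variants, [toy_gene], toy_genome)
        singles = [classify_variant(v, [toy_gene], toy_genome) for v in variants]
        assert batch == singles

    def test_error_names_variant_index(self, toy_gene, toy_genome):
        bad = [Variant(chrom="chrT", pos=15, ref="C", alt="A")]
        with pytest.raises(ConsistencyError, match="index 0"):
            annotate_all(bad, [toy_gene], toy_genome)
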