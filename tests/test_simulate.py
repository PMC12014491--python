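"""Generator properties: determinism, spectra, gene validity, segregation."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from bsamap.effects import extract_cds
from bsamap.models import MUT, WT, Variant
from bsamap.simulate import (
    CrossConfig,
    SimTruth,
    VariantTruth,
    expected_allelic_distance,
    haldane_r,
    map_distance_morgans,
    simulate_bulks,
    simulate_decay_series,
    simulate_ems_variants,
    simulate_expression,
    simulate_gene_models,
    simulate_genome,
    simulate_peaks,
)
from bsamap.scan import allelic_distance


class TestGenome:
    def test_deterministic_given_seed(self):
        cfg = CrossConfig(n_chrom=2, chrom_len=10_000, seed=3)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_n_chrom_records(self):
        cfg = CrossConfig(n_chrom=3, chrom_len=1_000, seed=0)
        assert [g.chrom_id for g in simulate_genome(cfg)] == ["chr1", "chr2", "chr3"]

    def test_base_composition_near_uniform(self):
        cfg = CrossConfig(n_chrom=1, chrom_len=1_000_000, seed=1)
        (g,) = simulate_genome(cfg)
        for base in "ACGT":
            assert g.sequence.count(base) / len(g) == pytest.approx(0.25, abs=0.01)


class TestGeneModels:
    def test_models_satisfy_invariants_and_translate_cleanly(self, small_dataset):
        seqs = {g.chrom_id: g.sequence for g in small_dataset.genome}
        for m in small_dataset.gene_models:
            m.validate()
            cds = extract_cds(m, seqs[m.chrom])
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert protein.endswith("*")
            assert "*" not in protein[:-1], f"internal stop in {m.gene_id}"

    def test_strands_roughly_balanced_over_100_genes(self):
        cfg = CrossConfig(n_chrom=2, chrom_len=1_500_000, n_genes=100, seed=7)
        rng = np.random.default_rng(cfg.seed)
        genome = simulate_genome(cfg, rng)
        models, _ = simulate_gene_models(genome, cfg.n_genes, rng)
        n_plus = sum(m.strand == "+" for m in models)
        assert 30 <= n_plus <= 70  # Binomial(100, 1/2) within ~4 sigma


class TestEmsVariants:
    def test_pure_transition_config_yields_only_ems_changes(self, small_dataset):
        cfg = CrossConfig(
            n_chrom=1, chrom_len=200_000, n_ems=200, n_genes=4,
            ems_transition_fraction=1.0, seed=5,
        )
        rng = np.random.default_rng(cfg.seed)
        genome = simulate_genome(cfg, rng)
        models, genome = simulate_gene_models(genome, cfg.n_genes, rng)
        variants, truth = simulate_ems_variants(genome, models, cfg, rng)
        assert all((v.ref, v.alt) in {("G", "A"), ("C", "T")} for v in variants)

    def test_exactly_one_causal_in_truth(self, small_dataset):
        truth = small_dataset.truth
        assert sum(t.is_causal for t in truth.variants) == 1
        assert tuple(truth.causal) in {t.key for t in truth.variants}

    def test_causal_is_protein_altering_ems_transition_in_cds(self, small_dataset):
        from bsamap.effects import classify_variant, genome_index, Impact

        chrom, pos, ref, alt = small_dataset.truth.causal
        assert (ref, alt) in {("G", "A"), ("C", "T")}
        ann = classify_variant(
            Variant(chrom=chrom, pos=pos, ref=ref, alt=alt),
            small_dataset.gene_models,
            genome_index(small_dataset.genome),
        )
        assert ann.gene_id == small_dataset.truth.causal_gene
        assert ann.impact in (Impact.MODERATE, Impact.HIGH)

    def test_transition_fraction_recovered_within_2pct(self):
        cfg = CrossConfig(
            n_chrom=1, chrom_len=500_000, n_ems=2_000, n_genes=4,
            ems_transition_fraction=0.8, seed=9,
        )
        rng = np.random.default_rng(cfg.seed)
        genome = simulate_genome(cfg, rng)
        models, genome = simulate_gene_models(genome, cfg.n_genes, rng)
        _, truth = simulate_ems_variants(genome, models, cfg, rng)
        frac = np.mean([t.is_ems_transition for t in truth.variants])
        assert frac == pytest.approx(0.8, abs=0.02)

    def test_truth_round_trips_through_json(self, small_dataset):
        text = small_dataset.truth.to_json()
        assert SimTruth.from_json(text) == small_dataset.truth


def _template_set(positions_bp, cm_per_mb=1.0, chrom="chr1"):
    """Causal at positions_bp[0]; truth carries Haldane r to each variant."""
    causal_pos = positions_bp[0]
    truths, variants = [], []
    for i, p in enumerate(positions_bp):
        r = haldane_r(map_distance_morgans(p - causal_pos, cm_per_mb))
        truths.append(
            VariantTruth(
                chrom=chrom, pos=p, ref="G", alt="A",
                is_ems_transition=True, in_panel=False,
                r_to_causal=r, is_causal=(i == 0),
            )
        )
        variants.append(Variant(chrom=chrom, pos=p, ref="G", alt="A"))
    truth = SimTruth(
        causal=(chrom, causal_pos, "G", "A"),
        causal_gene="geneX",
        causal_effect="missense",
        variants=truths,
    )
    return variants, truth


class TestBulks:
    def test_causal_site_frequencies_without_error(self):
        # every MUT individual is a heterozygous carrier -> f_mut = 0.5, f_wt = 0
        cfg = CrossConfig(error_rate=0.0, coverage=50.0, seed=2)
        variants, truth = _template_set([1_000])
        rng = np.random.default_rng(0)
        fm = []
        fw = []
        for _ in range(30):
            (v,) = simulate_bulks(variants, truth, cfg, rng)
            rec = allelic_distance(v)
            fm.append(rec.f_mut)
            fw.append(rec.f_wt)
        assert np.mean(fm) == pytest.approx(0.5, abs=0.05)
        assert np.mean(fw) == 0.0

    def test_unlinked_variant_distance_centred_on_zero(self):
        cfg = CrossConfig(error_rate=0.0, coverage=30.0, seed=2)
        variants, truth = _template_set([1_000])
        # move the variant to another chromosome: carrier probability 1/2 per bulk
        other = [Variant(chrom="chr2", pos=500, ref="G", alt="A")]
        truth.variants.append(
            VariantTruth(
                chrom="chr2", pos=500, ref="G", alt="A",
                is_ems_transition=True, in_panel=False, r_to_causal=0.5,
                is_causal=False,
            )
        )
        rng = np.random.default_rng(1)
        dists = []
        for _ in range(200):
            (v,) = simulate_bulks(other, truth, cfg, rng)
            dists.append(allelic_distance(v).distance)
        assert np.mean(dists) == pytest.approx(0.0, abs=0.02)

    def test_monte_carlo_matches_haldane_closed_form(self):
        # E[distance] = (1 - 2 r(m)) / 2 at m in {0, 0.05, 0.5} Morgans
        cfg = CrossConfig(error_rate=0.0, seed=0)  # n=80, 10x defaults
        positions = [1_000, 1_000 + 5_000_000, 1_000 + 50_000_000]
        variants, truth = _template_set(positions)
        dists = {p: [] for p in positions}
        for seed in range(50):
            rng = np.random.default_rng(seed)
            for v in simulate_bulks(variants, truth, cfg, rng):
                rec = allelic_distance(v)
                if rec.passes_depth:
                    dists[v.pos].append(rec.distance)
        for p, m in zip(positions, (0.0, 0.05, 0.5)):
            obs = np.array(dists[p])
            sem = obs.std(ddof=1) / math.sqrt(len(obs))
            assert abs(obs.mean() - expected_allelic_distance(m)) < 3 * sem


class TestDownstreamFixtures:
    def test_expressed_fraction_matches_configuration(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(2_000)]
        df, expressed = simulate_expression(ids, rng, expressed_fraction=0.625)
        value_cols = [c for c in df.columns if c != "gene_id"]
        observed = (df[value_cols] > 1.0).any(axis=1).mean()
        assert observed == pytest.approx(0.625, abs=0.05)
        # the table and the truth set agree exactly
        assert set(df.loc[(df[value_cols] > 1.0).any(axis=1), "gene_id"]) == expressed

    def test_forced_gene_is_always_expressed(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(50)]
        _, expressed = simulate_expression(
            ids, rng, expressed_fraction=0.0, always_expressed={"g7"}
        )
        assert expressed == {"g7"}

    def test_planted_proximal_peak_is_recorded_as_truth_target(self, small_dataset):
        rng = np.random.default_rng(8)
        peaks, planted = simulate_peaks(
            small_dataset.gene_models, ["fX"], rng, target_prob=1.0, decoy_prob=0.0
        )
        assert planted and all(p["is_target"] for p in planted)
        assert all(abs(p["offset"]) <= 800 for p in planted)

    def test_noiseless_decay_halves_at_tau(self):
        df = simulate_decay_series(
            np.random.default_rng(0), half_life=4.0, noise=0.0, n_replicates=1
        )
        s = df.set_index("time_h")["signal"]
        assert s[4.0] == pytest.approx(0.5 * s[0.0])
        assert s[8.0] == pytest.approx(0.25 * s[0.0])
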