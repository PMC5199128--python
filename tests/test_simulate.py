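"""Synthetic-data generator: determinism, planted structure, read statistics."""

import numpy as np
import pytest
from scipy.stats import poisson

from apadiv import pipeline
from apadiv.quantify import _VariantIndex
from apadiv.simulate import (SimConfig, generate_genome_pair, plant_genes_and_pas,
                             pool_mock_f1, simulate_3mrnaseq, simulate_3reads,
                             simulate_background_rnaseq)

SMALL = dict(n_genes=30, chrom_length_bp=120_000, read_depth_per_sample=20_000,
             background_depth=10_000)


class TestGenomePair:
    def test_fixed_seed_is_byte_identical(self):
        a = generate_genome_pair(SimConfig(seed=1, **SMALL))
        b = generate_genome_pair(SimConfig(seed=1, **SMALL))
        assert a.seqs_a == b.seqs_a and a.seqs_b == b.seqs_b
        assert [(v.chrom, v.pos, v.ref, v.alt) for v in a.vmap.variants] == [
            (v.chrom, v.pos, v.ref, v.alt) for v in b.vmap.variants
        ]

    def test_zero_rates_give_identical_genomes(self):
        g = generate_genome_pair(SimConfig(seed=1, snp_rate=0.0, indel_rate=0.0, **SMALL))
        assert g.seqs_a == g.seqs_b
        assert len(g.vmap.variants) == 0

    def test_snp_count_within_poisson_interval(self):
        # 100 kb at snp_rate 0.01: expected 1000, checked against the exact
        # central 99% Poisson interval
        cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length_bp=100_000,
                        snp_rate=0.01, indel_rate=0.0, n_genes=5)
        g = generate_genome_pair(cfg)
        n_snp = sum(1 for v in g.vmap.variants if v.vtype == "SNP")
        lo, hi = poisson.ppf([0.005, 0.995], 100_000 * 0.01)
        assert lo <= n_snp <= hi

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length_bp=0)
        with pytest.raises(ValueError):
            SimConfig(cis_effect_fraction=0.7, trans_effect_fraction=0.5)
        with pytest.raises(ValueError):
            SimConfig(snp_rate=-0.1)


class TestPlanting:
    def test_no_effects_when_fractions_zero(self):
        cfg = SimConfig(seed=5, cis_effect_fraction=0.0, trans_effect_fraction=0.0, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        assert all(p.effect == "none" for p in truth.all_pas())

    def test_usage_probabilities_sum_to_one_per_condition(self, bundle200):
        for gene in bundle200.truth.genes:
            for cond in ("BL", "SP", "F1_BL", "F1_SP"):
                assert gene.usage_vector(cond).sum() == pytest.approx(1.0)

    def test_cis_and_trans_expectation_structure(self, bundle200):
        """Cis: F1 allelic difference equals the parental difference; trans:
        F1 alleles agree while parents differ by the planted delta."""
        cfg = bundle200.config
        seen = {"cis": 0, "trans": 0}
        for p in bundle200.truth.all_pas():
            par = p.usage["BL"] - p.usage["SP"]
            f1 = p.usage["F1_BL"] - p.usage["F1_SP"]
            if p.effect == "cis":
                assert f1 == pytest.approx(par)
                seen["cis"] += 1
            elif p.effect == "trans":
                assert f1 == pytest.approx(0.0)
                assert abs(par) * 100 == pytest.approx(cfg.trans_delta_usage, abs=1e-6)
                seen["trans"] += 1
        assert seen["cis"] > 0 and seen["trans"] > 0

    def test_cis_flanks_differ_at_causal_variant_only(self, bundle200):
        from apadiv.flank import extract_flank

        g = bundle200.genomes
        vi = _VariantIndex(g.vmap)
        indels = {(v.chrom, v.pos) for v in g.vmap.variants if v.vtype != "SNP"}
        checked = 0
        for p in bundle200.truth.all_pas():
            if p.effect != "cis" or "AAUAAA" not in p.causal_variant:
                continue
            # an indel inside the flank shifts the positional alignment of the
            # two allele sequences, so restrict the base-by-base comparison to
            # SNP-only flanks
            if any((p.chrom, q) in indels for q in range(p.site - 101, p.site + 102)):
                continue
            fl = extract_flank(g.seqs_a, g.seqs_b, g.vmap, p.chrom, p.strand, p.site)
            if fl is None:
                continue
            diffs = {i - 100 for i, (x, y) in enumerate(zip(*fl)) if x != y}
            assert -23 in diffs  # the planted signal mutation
            # any other difference must coincide with a background variant
            n_bg = vi.count_overlapping(p.chrom, p.site - 101, p.site + 101)
            assert len(diffs) <= n_bg
            checked += 1
        assert checked > 0


class TestReadStreams:
    def test_zero_jitter_zero_noise_reads_sit_on_true_sites(self):
        cfg = SimConfig(seed=9, cleavage_jitter_sd_nt=0.0,
                        background_noise_read_fraction=0.0, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        reads = simulate_3reads(truth, g, cfg)
        sites_a = {(p.chrom, p.strand, p.site) for p in truth.all_pas()}
        sites_b = {
            (p.chrom, p.strand, g.vmap.liftover_position(p.chrom, p.site))
            for p in truth.all_pas()
        }
        for r in reads:
            expected = sites_a if r.allele == "BL" else sites_b
            assert (r.chrom, r.strand, r.pos) in expected

    def test_read_totals_conserved(self):
        cfg = SimConfig(seed=9, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        reads = simulate_3reads(truth, g, cfg)
        # 2 strains x 2 replicates x configured depth
        assert len(reads) == 4 * cfg.read_depth_per_sample

    def test_pass_fraction_matches_tail_distribution(self):
        # P(T >= 2) = 0.4 at n = 10,000 true-site reads: binomial 4-sigma band
        cfg = SimConfig(seed=13, n_genes=30, chrom_length_bp=120_000,
                        read_depth_per_sample=10_000, background_depth=5_000,
                        tail_T_distribution={0: 0.3, 1: 0.3, 2: 0.4},
                        background_noise_read_fraction=0.0)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        reads = [r for r in simulate_3reads(truth, g, cfg)
                 if r.sample == "3READS_BL" and r.replicate == 1]
        frac = np.mean([r.tail_t >= 2 for r in reads])
        tol = 4 * np.sqrt(0.4 * 0.6 / len(reads))
        assert abs(frac - 0.4) < tol

    def test_zero_mispriming_zero_jitter_reads_inside_windows(self):
        cfg = SimConfig(seed=11, mispriming_rate=0.0, cleavage_jitter_sd_nt=0.0, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        reads = simulate_3mrnaseq(truth, g, cfg, "parentBL")
        sites = {(p.chrom, p.strand, p.site) for p in truth.all_pas()}
        assert all((r.chrom, r.strand, r.pos) in sites for r in reads)

    def test_f1_variant_overlap_matches_closed_form(self):
        """Fraction of F1 reads overlapping >= 1 variant follows the geometric
        no-variant probability (1 - (1-rate)^L) averaged over read placements."""
        cfg = SimConfig(seed=17, snp_rate=0.01, indel_rate=0.0, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        reads = simulate_3mrnaseq(truth, g, cfg, "F1")
        vi = _VariantIndex(g.vmap)
        from apadiv.quantify import read_interval

        hits = [vi.count_overlapping(r.chrom, *read_interval(r, cfg.read_length)) > 0
                for r in reads]
        expected = 1 - (1 - cfg.snp_rate) ** cfg.read_length
        # read anchors cluster on a limited set of windows, so allow a wide
        # band around the closed form (site-to-site variance dominates)
        assert abs(np.mean(hits) - expected) < 0.12

    def test_trans_effect_parental_shift_without_allelic_shift(self):
        cfg = SimConfig(seed=19, n_genes=40, chrom_length_bp=200_000,
                        cis_effect_fraction=0.0, trans_effect_fraction=0.5,
                        read_depth_per_sample=80_000, background_depth=10_000)
        b = pipeline.simulate_all(cfg, with_3reads=False)
        ref = pipeline.reference_from_truth(b)
        quant = pipeline.quantify_all(b, ref)
        par = quant.parental.set_index("pas_id")
        alle = quant.allelic.set_index("pas_id")
        gene_tot = {c: quant.parental.groupby("gene_id")[c].sum() for c in ("BL", "SP")}
        gene_tot_f1 = {c: quant.allelic.groupby("gene_id")[c].sum() for c in ("F1_BL", "F1_SP")}
        checked = 0
        for p in b.truth.all_pas():
            if p.effect != "trans":
                continue
            # the +/-3-point empirical band applies at gene depth >= 2,000
            if gene_tot["BL"][p.gene_id] < 2000 or gene_tot["SP"][p.gene_id] < 2000:
                continue
            u_bl = 100 * par.loc[p.pas_id, "BL"] / gene_tot["BL"][p.gene_id]
            u_sp = 100 * par.loc[p.pas_id, "SP"] / gene_tot["SP"][p.gene_id]
            f_bl = 100 * alle.loc[p.pas_id, "F1_BL"] / gene_tot_f1["F1_BL"][p.gene_id]
            f_sp = 100 * alle.loc[p.pas_id, "F1_SP"] / gene_tot_f1["F1_SP"][p.gene_id]
            assert u_bl - u_sp == pytest.approx(p.true_delta, abs=3.0)
            assert abs(f_bl - f_sp) < 3.0
            checked += 1
        assert checked >= 5


class TestPoolingAndBackground:
    def test_mock_pool_concatenates_and_relabels(self):
        cfg = SimConfig(seed=23, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        bl = simulate_3mrnaseq(truth, g, cfg, "parentBL")
        sp = simulate_3mrnaseq(truth, g, cfg, "parentSP")
        mock = pool_mock_f1(bl, sp)
        assert len(mock) == len(bl) + len(sp)
        assert all(r.sample == "mock" for r in mock)
        # splitting by true allele recovers the inputs exactly (modulo label)
        back_bl = [r for r in mock if r.allele == "BL"]
        assert [(r.chrom, r.pos, r.read_id) for r in back_bl] == [
            (r.chrom, r.pos, r.read_id) for r in bl
        ]
        assert pool_mock_f1(bl, []) == [r for r in mock if r.allele == "BL"]

    def test_background_confined_to_genes_and_deterministic(self):
        cfg = SimConfig(seed=29, **SMALL)
        g = generate_genome_pair(cfg)
        _, truth = plant_genes_and_pas(g, cfg)
        bg1 = simulate_background_rnaseq(truth, cfg, g)
        bg2 = simulate_background_rnaseq(truth, cfg, g)
        assert bg1["BL"].equals(bg2["BL"])
        spans = {ge.gene_id: (ge.start, ge.end) for ge in truth.genes}
        df = bg1["BL"]
        for _, row in df.iterrows():
            lo, hi = spans[row["name"]]
            assert lo <= row["start"] < hi
        # per-gene totals proportional to weights (multinomial, loose bound)
        weights = {ge.gene_id: ge.weight for ge in truth.genes}
        w = np.array([weights[n] for n in df["name"].value_counts().index])
        obs = df["name"].value_counts().to_numpy()
        exp = w / sum(weights.values()) * len(df)
        assert np.corrcoef(obs, exp)[0, 1] > 0.99
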