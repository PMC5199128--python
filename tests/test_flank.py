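"""Flank-sequence features: windows, densities, hexamers, motifs, poly(U)."""

import numpy as np
import pandas as pd
import pytest

from apadiv.flank import (ELEMENT_WINDOWS, FlankProfile, build_flank_profiles,
                          compare_hexamers_groups, extract_flank, hexamer_counts,
                          hexamer_quadrants, motif_intact, motif_mutated,
                          motif_presence_effect, polyu_tract_analysis,
                          select_controls, sliding_density, variant_density)
from apadiv.liftover import Variant, VariantMap
from apadiv.simulate import revcomp


def profile(seq_bl, seq_sp=None, delta=0.0, pas_id="p"):
    seq_sp = seq_sp if seq_sp is not None else seq_bl
    assert len(seq_bl) == 201 and len(seq_sp) == 201
    return FlankProfile(pas_id, "chr1", "+", 1000, seq_bl, seq_sp, delta)


def flank_with(upstream_insert, offset, base="A"):
    """201-nt RNA flank with a motif written at the given sense offset."""
    seq = list(base * 201)
    for i, ch in enumerate(upstream_insert):
        seq[100 + offset + i] = ch
    return "".join(seq)


class TestWindowsGeometry:
    def test_element_window_lengths(self):
        lengths = {k: hi - lo for k, (lo, hi) in ELEMENT_WINDOWS.items()}
        assert lengths == {"AUE": 60, "CUE": 40, "CDE": 40, "ADE": 60}

    def test_region_slicing(self):
        p = profile(flank_with("GGG", -40))
        assert p.region("BL", -40, -37) == "GGG"
        assert len(p.region("BL", -100, 0)) == 100
        assert len(p.region("BL", 1, 101)) == 100


class TestExtraction:
    def test_strand_symmetry(self):
        """Mirroring a pAs onto the minus strand leaves the transcript-
        oriented flank unchanged."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=2001))
        vmap = VariantMap([], {"chr1": 2001})
        seqs = {"chr1": seq}
        plus = extract_flank(seqs, seqs, vmap, "chr1", "+", 1000)
        mirrored = {"chr1": revcomp(seq)}
        minus = extract_flank(mirrored, mirrored, vmap, "chr1", "-", 1000)
        assert plus[0] == minus[0]

    def test_unmappable_site_skipped(self):
        seq = {"chr1": "A" * 2001}
        vmap = VariantMap([Variant("chr1", 995, "A" * 10, "")], {"chr1": 2001})
        seqs_b = {"chr1": vmap.apply_to_sequence("chr1", seq["chr1"])}
        assert extract_flank(seq, seqs_b, vmap, "chr1", "+", 1000) is None
        records = pd.DataFrame([{"pas_id": "p", "chrom": "chr1", "strand": "+",
                                 "site": 1000}])
        assert build_flank_profiles(records, seq, seqs_b, vmap) == []


class TestVariantDensity:
    def records(self):
        return pd.DataFrame([{"pas_id": "p", "chrom": "chr1", "strand": "+",
                              "site": 1000}])

    def test_density_arithmetic(self):
        vmap = VariantMap([Variant("chr1", 1000 + off, "A", "G")
                           for off in (-60, -20, 10, 80)], {"chr1": 10_000})
        out = variant_density(self.records(), vmap)
        assert out.loc[0, "density"] == pytest.approx(4 / 200)
        assert out.loc[0, "AUE"] == pytest.approx(1 / 60)
        assert out.loc[0, "CUE"] == pytest.approx(1 / 40)
        assert out.loc[0, "CDE"] == pytest.approx(1 / 40)
        assert out.loc[0, "ADE"] == pytest.approx(1 / 60)

    def test_zero_variants(self):
        out = variant_density(self.records(), VariantMap([], {"chr1": 10_000}))
        assert out.loc[0, "density"] == 0.0

    def test_minus_strand_offsets_mirror(self):
        vmap = VariantMap([Variant("chr1", 1020, "A", "G")], {"chr1": 10_000})
        rec = self.records()
        rec["strand"] = "-"
        out = variant_density(rec, vmap)
        assert out.loc[0, "CUE"] == pytest.approx(1 / 40)  # +20 genomic = -20 sense


class TestSlidingDensity:
    def test_window_count_is_193(self):
        vmap = VariantMap([Variant("chr1", 985, "A", "G")], {"chr1": 10_000})
        recs = pd.DataFrame([{"pas_id": f"p{i}", "chrom": "chr1", "strand": "+",
                              "site": 1000} for i in range(3)])
        out = sliding_density(recs, recs, vmap)
        assert len(out) == 193

    def test_identical_sets_never_significant(self):
        vmap = VariantMap([Variant("chr1", 985, "A", "G")], {"chr1": 10_000})
        recs = pd.DataFrame([{"pas_id": f"p{i}", "chrom": "chr1", "strand": "+",
                              "site": 1000 + 300 * i} for i in range(4)])
        out = sliding_density(recs, recs, vmap)
        assert not out["significant"].any()

    def test_small_sets_rejected(self):
        vmap = VariantMap([], {"chr1": 10_000})
        rec = pd.DataFrame([{"pas_id": "p", "chrom": "chr1", "strand": "+", "site": 1000}])
        with pytest.raises(ValueError):
            sliding_density(rec, rec, vmap)


class TestHexamers:
    def test_counts_match_naive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            counts = hexamer_counts(seq)
            for h in set(counts) | {"AAAAAA", seq[:6]}:
                naive = sum(seq[i:i + 6] == h for i in range(len(seq) - 5))
                assert counts.get(h, 0) == naive
            assert sum(counts.values()) == len(seq) - 5

    def test_quadrant_signs(self):
        # group 1 (BL-biased): AAUAAA intact in BL only; group 2: in SP only
        g1 = profile(flank_with("AAUAAA", -25), flank_with("AAGAAA", -25), delta=30)
        g2 = profile(flank_with("AAGAAA", -25), flank_with("AAUAAA", -25), delta=-30)
        table = hexamer_quadrants([g1, g2]).set_index("hexamer")
        assert table.loc["AAUAAA", "diff_group1"] == 1
        assert table.loc["AAUAAA", "diff_group2"] == -1
        assert table.loc["AAUAAA", "quadrant"] == "enhancer"

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            hexamer_quadrants([profile(flank_with("AAUAAA", -25), delta=30)])

    def test_group_frequency_totals(self):
        profs = [profile(flank_with("AAUAAA", -25)) for _ in range(3)]
        ctl = [profile("A" * 201) for _ in range(2)]
        out = compare_hexamers_groups(profs, ctl)
        assert out["count_trans"].sum() == 3 * 95
        assert out["count_control"].sum() == 2 * 95


class TestControlsAndMotifs:
    def test_select_controls_rules(self):
        rec = pd.DataFrame({
            "pas_id": ["a", "b", "c"],
            "p_adj": [0.8, 0.8, 0.3],
            "delta_usage": [2.0, 7.0, 1.0],
        })
        assert set(select_controls(rec)["pas_id"]) == {"a"}

    def test_motif_mutated_definition(self):
        p = profile(flank_with("AAUAAA", -25), flank_with("AAUAAG", -25))
        assert motif_intact(p, "BL", "AAUAAA")
        assert not motif_intact(p, "SP", "AAUAAA")
        assert motif_mutated(p, "AAUAAA")
        both = profile(flank_with("AAUAAA", -25))
        assert not motif_mutated(both, "AAUAAA")

    def test_presence_effect_orientation(self):
        one = [profile(flank_with("AAUAAA", -25), flank_with("AAGAAA", -25),
                       delta=20, pas_id=f"a{i}") for i in range(6)]
        one += [profile(flank_with("AAGAAA", -25), flank_with("AAUAAA", -25),
                        delta=-20, pas_id=f"b{i}") for i in range(6)]
        ref = [profile("A" * 201, delta=d, pas_id=f"c{i}")
               for i, d in enumerate(np.linspace(-2, 2, 8))]
        out = motif_presence_effect(one + ref, "AAUAAA")
        assert out["median_oriented_delta"] == pytest.approx(20.0)
        assert out["p_value"] < 0.01


class TestPolyU:
    def flankU(self, n_u, delta, pas_id):
        # U-run placed at -60; poly(A) background cannot extend it
        return profile(flank_with("U" * 6, -60), flank_with("U" * n_u + "C" * (6 - n_u), -60),
                       delta=delta, pas_id=pas_id)

    def test_grouping_rules(self):
        profs = [self.flankU(2, -25, "deep"),
                 profile(flank_with("U" * 6, -60), delta=0.5, pas_id="bg")]
        out = polyu_tract_analysis(profs, 6).set_index("group")
        assert out.loc["U_2", "n"] == 1
        assert out.loc["Bg", "n"] == 1
        # delta oriented to the intact (BL) allele
        assert out.loc["U_2", "median_oriented_delta"] == pytest.approx(-25)

    def test_orientation_flips_for_sp_intact(self):
        p = profile(flank_with("U" * 3 + "C" * 3, -60), flank_with("U" * 6, -60),
                    delta=25, pas_id="x")
        bg = profile(flank_with("U" * 6, -60), delta=0.0, pas_id="bg")
        out = polyu_tract_analysis([p, bg], 6).set_index("group")
        assert out.loc["U_3", "median_oriented_delta"] == pytest.approx(-25)

    def test_short_tract_length_rejected(self):
        with pytest.raises(ValueError):
            polyu_tract_analysis([], 2)
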