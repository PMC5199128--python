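"""Cluster calling, enrichment, dominance p and the empirical FDR."""

import numpy as np
import pandas as pd
import pytest

from apadiv.cluster import (BackgroundIndex, attach_enrichment, cluster_sites,
                            empirical_p, enrichment_stats, estimate_q,
                            reproducibility_filter, split_reads_by_tail,
                            windows_48)
from apadiv.types import PasCluster, TailRead


def read(pos, t, rep=1, strand="+"):
    return TailRead("chr1", pos, strand, t, "s", rep, "BL", f"r{pos}-{t}")


def brute_force_cluster(sites: dict[int, int], gap: int = 24):
    """Direct transcription of the published clustering narrative.

    Single-linkage grouping of sites within `gap`; small groups become one
    cluster with the max-coverage site as representative; wide groups are
    peeled around the max-coverage site and the leftovers re-clustered.
    Independent of the package implementation.
    """
    out = []

    def rep_of(group):
        return max(group, key=lambda x: (sites[x], -x))

    def regroup(positions):
        groups, cur = [], []
        for p in sorted(positions):
            if cur and p - cur[-1] > gap:
                groups.append(cur)
                cur = []
            cur.append(p)
        if cur:
            groups.append(cur)
        return groups

    def handle(group):
        if not group:
            return
        if group[-1] - group[0] <= gap:
            out.append((rep_of(group), tuple(group)))
            return
        rep = rep_of(group)
        members = [p for p in group if abs(p - rep) <= gap]
        out.append((rep, tuple(members)))
        for sub in regroup(p for p in group if abs(p - rep) > gap):
            handle(sub)

    for g in regroup(sites):
        handle(g)
    return sorted((r, m, sum(sites[x] for x in m)) for r, m in out)


class TestSplit:
    def test_tail_thresholds(self):
        reads = [read(1, 0), read(2, 1), read(3, 2), read(4, 5)]
        pas, pseudo = split_reads_by_tail(reads)
        assert [r.tail_t for r in pas] == [2, 5]
        assert [r.tail_t for r in pseudo] == [0]
        assert len(pas) + len(pseudo) <= len(reads)  # 1T reads support neither

    def test_negative_tail_raises(self):
        with pytest.raises(ValueError):
            split_reads_by_tail([read(1, -1)])


class TestClusterSites:
    def test_two_components_split_by_gap(self):
        clusters = cluster_sites({100: 5, 110: 3, 160: 2}, "chr1", "+")
        assert [(c.site, c.r) for c in clusters] == [(100, 8), (160, 2)]

    def test_wide_component_absorbed_by_peak(self):
        clusters = cluster_sites({0: 1, 10: 5, 20: 1, 30: 1}, "chr1", "+")
        assert [(c.site, c.r) for c in clusters] == [(10, 8)]

    def test_single_site(self):
        clusters = cluster_sites({500: 7}, "chr1", "-")
        assert [(c.site, c.r, c.size) for c in clusters] == [(500, 7, 1)]

    def test_tie_breaks_toward_smaller_coordinate(self):
        clusters = cluster_sites({100: 4, 110: 4}, "chr1", "+")
        assert clusters[0].site == 100

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            pos = rng.choice(400, size=n, replace=False)
            sites = {int(p): int(rng.integers(1, 10)) for p in pos}
            got = sorted(
                (c.site, tuple(range(c.span_start, c.span_end + 1)), c.r)
                for c in cluster_sites(sites, "chr1", "+")
            )
            expected = brute_force_cluster(sites)
            got_cmp = [(r, m) for r, _, m in got]
            exp_cmp = [(r, m) for r, _, m in expected]
            assert got_cmp == exp_cmp
            # partition: every read in exactly one cluster
            assert sum(m for _, m in got_cmp) == sum(sites.values())


class TestEnrichment:
    def test_arithmetic_forced_by_formula(self):
        c = PasCluster("chr1", "+", 1000, 988, 1011, r=12)  # size 24
        bg = BackgroundIndex(pd.DataFrame({
            "chrom": ["chr1"] * 55, "start": np.linspace(600, 1040, 55).astype(int),
            "end": 0, "name": ".", "score": 0, "strand": ["+"] * 55,
        }))
        _, e = enrichment_stats(c, bg, pseudocount=0.0)
        assert e == pytest.approx((12 / 24) / (55 / 550))

    def test_pseudocount_keeps_e_finite_without_background(self):
        c = PasCluster("chr1", "+", 1000, 1000, 1000, r=3)
        bg = BackgroundIndex(pd.DataFrame())
        _, e = enrichment_stats(c, bg, pseudocount=1.0)
        assert np.isfinite(e) and e == pytest.approx(3 / (1 / 550))

    def test_true_sites_dominate_noise_in_enrichment(self, discovery_bundle):
        """E of planted pAs clusters exceeds E of internal-noise clusters in
        nearly all pairings on a seeded simulation."""
        from apadiv.cluster import call_clusters, split_reads_by_tail

        b = discovery_bundle
        reads = [r for r in b.reads_3reads
                 if r.sample == "3READS_BL" and r.replicate == 1]
        pass_reads, _ = split_reads_by_tail(reads)
        clusters = call_clusters(pass_reads)
        attach_enrichment(clusters, BackgroundIndex(b.background["BL"]))
        sites = {}
        for p in b.truth.all_pas():
            sites.setdefault((p.chrom, p.strand), []).append(p.site)
        true_e, noise_e = [], []
        for c in clusters:
            near = sites.get((c.chrom, c.strand), [])
            (true_e if any(abs(c.site - s) <= 24 for s in near) else noise_e).append(c.e)
        true_e, noise_e = np.array(true_e), np.array(noise_e)
        assert len(true_e) > 50 and len(noise_e) > 20
        frac = (true_e[:, None] > noise_e[None, :]).mean()
        assert frac >= 0.95


class TestEmpiricalP:
    def make(self, pairs):
        return [PasCluster("chr1", "+", i, i, i, r=r, e=e)
                for i, (r, e) in enumerate(pairs)]

    def test_dominance_counts(self):
        cl = self.make([(10, 5), (8, 6), (12, 7), (1, 1)])
        empirical_p(cl)
        assert cl[3].p_emp == pytest.approx(0.75)  # dominated by a, b, c
        assert cl[2].p_emp == 0.0  # nothing beats it on both axes

    def test_identical_clusters_all_zero(self):
        cl = self.make([(5, 5)] * 4)
        empirical_p(cl)
        assert all(c.p_emp == 0.0 for c in cl)

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(0)
        pairs = [(int(r), float(e)) for r, e in zip(rng.integers(1, 50, 30),
                                                    rng.random(30) * 10)]
        cl = self.make(pairs)
        empirical_p(cl)
        perm = list(np.array(cl, dtype=object)[rng.permutation(30)])
        empirical_p(perm)
        by_site = {c.site: c.p_emp for c in perm}
        assert all(c.p_emp == by_site[c.site] for c in cl)


class TestEstimateQ:
    def make(self, pairs, start=0):
        return [PasCluster("chr1", "+", start + i, start + i, start + i, r=r, e=e)
                for i, (r, e) in enumerate(pairs)]

    def test_q_is_ratio_of_dominance_ps(self):
        # target (5,5): dominated by 1 of 10 real (Pi(2T)=0.1); pseudo set of
        # equal size is used whole in every subsample, 5 dominators -> 0.5
        real = self.make([(5, 5), (10, 10)] + [(1, 1)] * 8)
        pseudo = self.make([(6, 6)] * 5 + [(1, 1)] * 5, start=100)
        estimate_q(real, pseudo, n_subsamples=10, seed=0)
        assert real[0].p_emp == pytest.approx(0.1)
        assert real[0].q == pytest.approx((5 / 10) / 0.1 if (5 / 10) / 0.1 <= 1 else 1.0)
        assert real[0].q == 1.0  # 0.5 / 0.1 clamps

    def test_q_clamped_and_zero_conventions(self):
        real = self.make([(10, 10), (5, 5), (1, 1)])
        pseudo = self.make([(0, 0)] * 3, start=100)
        estimate_q(real, pseudo, n_subsamples=5, seed=1)
        assert real[0].q == 0.0  # Pi(2T) = 0 -> Q = 0 by convention
        assert all(0.0 <= c.q <= 1.0 for c in real)

    def test_pseudo_equal_to_real_gives_q_one_for_dominated(self):
        rng = np.random.default_rng(3)
        pairs = [(int(r), float(e)) for r, e in zip(rng.integers(1, 50, 20),
                                                    rng.random(20) * 10)]
        real = self.make(pairs)
        pseudo = self.make(pairs, start=100)
        estimate_q(real, pseudo, n_subsamples=3, seed=2)
        for c in real:
            if c.p_emp > 0:
                assert c.q == pytest.approx(1.0)

    def test_input_validation(self):
        real = self.make([(1, 1)])
        with pytest.raises(ValueError):
            estimate_q(real, [], n_subsamples=10)
        with pytest.raises(ValueError):
            estimate_q(real, self.make([(1, 1)], start=10), n_subsamples=0)


class TestReproducibility:
    def cl(self, site, q, r=10, rep=0):
        c = PasCluster("chr1", "+", site, site, site, r=r, replicate=rep)
        c.q = q
        return c

    def test_cluster_in_one_replicate_only_dropped(self):
        kept = reproducibility_filter([self.cl(100, 0.01)], [self.cl(500, 0.01)])
        assert kept == []

    def test_high_q_in_either_replicate_drops_pair(self):
        kept = reproducibility_filter([self.cl(100, 0.01)], [self.cl(105, 0.2)])
        assert kept == []

    def test_matched_low_q_pair_kept_with_summed_r(self):
        kept = reproducibility_filter([self.cl(100, 0.01, r=10)],
                                      [self.cl(105, 0.02, r=20)])
        assert len(kept) == 1
        assert kept[0].r == 30
        assert kept[0].site == 105  # higher-R member's representative
        assert kept[0].q == 0.02


class TestWindows:
    def test_plus_strand_window(self):
        c = PasCluster("chr1", "+", 1000, 1000, 1000, r=1)
        (w,) = windows_48([c], {"chr1": 10_000})
        assert (w.start, w.end, w.anchor) == (976, 1025, 1000)
        assert w.end - w.start == 49  # -24..+24 inclusive

    def test_minus_strand_symmetric(self):
        c = PasCluster("chr1", "-", 1000, 1000, 1000, r=1)
        (w,) = windows_48([c], {"chr1": 10_000})
        assert (w.start, w.end) == (976, 1025)

    def test_clipped_at_chromosome_start(self):
        c = PasCluster("chr1", "+", 10, 10, 10, r=1)
        (w,) = windows_48([c], {"chr1": 10_000})
        assert (w.start, w.end) == (0, 35)
        assert w.end - w.start < 49
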