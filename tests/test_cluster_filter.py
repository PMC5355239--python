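from itertools import permutations, product

import numpy as np
import pytest

from spongeclip.annotation import GenomicInterval
from spongeclip.cluster_filter import (
    FilterConfig,
    FilterError,
    FilteredCluster,
    cluster_overlap,
    filter_utr3,
    gene_hit_table,
    gene_overlap,
    seed_proximity_filter,
    utr_match_to_genomic,
)
from spongeclip.parclip import Cluster
from spongeclip.seeds import SeedMatch


def cluster(start, end, mode=None, gene="g1", label="3UTR", chrom="c", strand="+"):
    mode = mode if mode is not None else start
    return Cluster(chrom, strand, start, end, 6, 3, (mode,), mode,
                   gene_id=gene, region_label=label)


def fc(c, *matches):
    return FilteredCluster(c, tuple(matches))


class TestFilterUtr3:
    def test_keeps_only_3utr(self):
        cds = cluster(0, 20, label="CDS")
        utr = cluster(30, 50, label="3UTR")
        assert filter_utr3([cds, utr]) == [utr]

    def test_empty_input(self):
        assert filter_utr3([]) == []

    def test_unannotated_cluster_errors(self):
        c = Cluster("c", "+", 0, 20, 6, 3, (5,), 5)
        with pytest.raises(FilterError, match="annotate"):
            filter_utr3([c])


class TestProjection:
    def test_plus_strand_identity(self):
        utr = [GenomicInterval("c", 100, 200, "+")]
        m = SeedMatch("g1", 10, 7, "7mer-m8", "f")
        assert utr_match_to_genomic(m, utr) == [(110, 117)]

    def test_minus_strand_reverses(self):
        utr = [GenomicInterval("c", 100, 200, "-")]
        m = SeedMatch("g1", 10, 7, "7mer-m8", "f")
        # UTR offset 0 is the transcript 5' end = genomic end on '-'
        assert utr_match_to_genomic(m, utr) == [(183, 190)]

    def test_split_across_exons(self):
        utr = [GenomicInterval("c", 100, 110, "+"), GenomicInterval("c", 200, 250, "+")]
        m = SeedMatch("g1", 6, 8, "8mer", "f")
        assert utr_match_to_genomic(m, utr) == [(106, 110), (200, 204)]

    def test_past_end_errors(self):
        utr = [GenomicInterval("c", 100, 110, "+")]
        with pytest.raises(FilterError, match="extends past"):
            utr_match_to_genomic(SeedMatch("g1", 8, 7, "7mer-m8", "f"), utr)


class TestSeedProximity:
    UTR = {"g1": [GenomicInterval("c", 100, 300, "+")]}

    def _run(self, clusters, matches, **kwargs):
        cfg = FilterConfig(**kwargs)
        return seed_proximity_filter(clusters, {"g1": matches}, self.UTR, cfg)

    def test_site_at_mode_retained(self):
        c = cluster(140, 170, mode=150)
        m = SeedMatch("g1", 50, 7, "7mer-m8", "f")  # genomic start 150
        (out,) = self._run([c], [m])
        assert out.matches == (m,)

    def test_site_beyond_window_dropped(self):
        c = cluster(140, 170, mode=150)
        # genomic interval [158, 165): 8 bp downstream of the mode, > 3 away
        m = SeedMatch("g1", 58, 7, "7mer-m8", "f")
        assert self._run([c], [m]) == []

    def test_interval_intersection_is_inclusive(self):
        c = cluster(140, 170, mode=150)
        # site starts exactly at mode + 3
        m = SeedMatch("g1", 53, 7, "7mer-m8", "f")
        assert len(self._run([c], [m])) == 1
        # site ends exactly at mode - 3 (end-inclusive via intersection)
        m2 = SeedMatch("g1", 40, 7, "7mer-m8", "f")  # [140,147) vs window [147,153]
        assert self._run([c], [m2]) == []

    def test_only_6mer_in_window_dropped(self):
        c = cluster(140, 170, mode=150)
        m = SeedMatch("g1", 50, 6, "6mer", "f")
        assert self._run([c], [m]) == []
        assert len(self._run([c], [m], exclude_6mer=False)) == 1

    def test_start_distance_mode(self):
        c = cluster(140, 170, mode=150)
        m = SeedMatch("g1", 46, 7, "7mer-m8", "f")  # starts 4 bp upstream, overlaps mode
        assert len(self._run([c], [m])) == 1
        assert self._run([c], [m], window_mode="start") == []

    def test_monotone_in_window_and_6mer_flag(self):
        rng = np.random.default_rng(4)
        clusters = [cluster(100 + 40 * i, 140 + 40 * i, mode=110 + 40 * i) for i in range(4)]
        matches = [
            SeedMatch("g1", int(rng.integers(0, 190)), 7, "7mer-m8", "f")
            for _ in range(10)
        ] + [SeedMatch("g1", int(rng.integers(0, 190)), 6, "6mer", "f") for _ in range(10)]
        prev = None
        for w in (8, 5, 3, 1, 0):
            out = {
                id(o.cluster)
                for o in self._run(clusters, matches, seed_mode_window_nt=w,
                                   exclude_6mer=False)
            }
            if prev is not None:
                assert out <= prev
            prev = out
        for w in (8, 3, 0):
            with_6 = self._run(clusters, matches, seed_mode_window_nt=w, exclude_6mer=False)
            without = self._run(clusters, matches, seed_mode_window_nt=w, exclude_6mer=True)
            assert {id(o.cluster) for o in without} <= {id(o.cluster) for o in with_6}


class TestGeneOverlap:
    def test_intersection(self):
        res = gene_overlap([{"A", "B", "C"}, {"B", "C"}, {"B"}])
        assert res["genes_in_all"] == {"B"}

    def test_fraction_of_smaller_set(self):
        big = {f"g{i}" for i in range(10)}
        small = {"g0", "g1", "g2", "g3", "x"}
        res = gene_overlap([big, small])
        assert res["pairwise"][(0, 1)]["fraction_of_smaller"] == pytest.approx(0.8)

    def test_identical_replicas_100_percent(self):
        s = {"a", "b"}
        res = gene_overlap([s, set(s)])
        assert res["pairwise"][(0, 1)]["fraction_of_smaller"] == 1.0

    def test_intersection_subset_of_each_replica(self):
        rng = np.random.default_rng(1)
        reps = [set(rng.choice(50, 20, replace=False).tolist()) for _ in range(3)]
        res = gene_overlap(reps)
        for rep in reps:
            assert res["genes_in_all"] <= rep

    def test_needs_two_replicas(self):
        with pytest.raises(FilterError):
            gene_overlap([{"a"}])


class TestClusterOverlap:
    def test_nine_bp_overlap_not_grouped(self):
        cfg = FilterConfig()
        reps = [[cluster(100, 130)], [cluster(121, 140)]]
        assert cluster_overlap(reps, cfg) == []

    def test_ten_bp_boundary_grouped(self):
        cfg = FilterConfig()
        reps = [[cluster(100, 130)], [cluster(120, 140)]]
        assert len(cluster_overlap(reps, cfg)) == 1

    def test_chain_without_pairwise_overlap_rejected(self):
        # A∩B = 12, B∩C = 12, but A∩C = 0: the pairwise rule fails
        cfg = FilterConfig()
        a, b, c = cluster(100, 130), cluster(118, 160), cluster(148, 180)
        assert cluster_overlap([[a], [b], [c]], cfg) == []

    def test_core_mode_equivalent_for_intervals(self):
        """For 1-D intervals the common intersection equals the minimum
        pairwise overlap, so the two overlap criteria must agree."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            reps = []
            for _r in range(3):
                clusters = []
                for slot in range(int(rng.integers(1, 4))):
                    base = 100 * slot + int(rng.integers(0, 50))
                    clusters.append(cluster(base, base + int(rng.integers(12, 70))))
                reps.append(clusters)
            pairwise = cluster_overlap(reps, FilterConfig(overlap_mode="pairwise"))
            core = cluster_overlap(reps, FilterConfig(overlap_mode="core"))
            assert pairwise == core

    def test_each_cluster_used_once(self):
        cfg = FilterConfig()
        reps = [[cluster(100, 130), cluster(105, 135)], [cluster(100, 130)]]
        groups = cluster_overlap(reps, cfg)
        assert len(groups) == 1

    def test_replica_order_invariant_count_on_toy_instances(self):
        cfg = FilterConfig()
        rng = np.random.default_rng(8)
        for _ in range(20):
            reps = []
            for _r in range(3):
                clusters = []
                for slot in range(int(rng.integers(1, 5))):
                    base = 200 * slot + int(rng.integers(0, 30))
                    clusters.append(cluster(base, base + int(rng.integers(20, 45))))
                reps.append(clusters)
            counts = {
                len(cluster_overlap([reps[i] for i in perm], cfg))
                for perm in permutations(range(3))
            }
            assert len(counts) == 1

    def test_groups_satisfy_rule_and_match_exhaustive_maximum(self):
        """Greedy grouping equals the exhaustive maximum number of disjoint
        valid groups on small instances."""
        cfg = FilterConfig()
        rng = np.random.default_rng(9)

        def exhaustive_max(reps):
            best = 0
            choices = [list(range(len(r))) for r in reps]

            def search(used, count, combos):
                nonlocal best
                best = max(best, count)
                for combo in combos:
                    if any((ri, ci) in used for ri, ci in enumerate(combo)):
                        continue
                    search(used | {(ri, ci) for ri, ci in enumerate(combo)}, count + 1, combos)

            valid = []
            for combo in product(*choices):
                chosen = [reps[r][c] for r, c in enumerate(combo)]
                if all(
                    min(x.end, y.end) - max(x.start, y.start) >= cfg.min_cluster_overlap_bp
                    for i, x in enumerate(chosen)
                    for y in chosen[i + 1 :]
                ):
                    valid.append(combo)
            search(frozenset(), 0, valid)
            return best

        for _ in range(15):
            reps = []
            for _r in range(2 + int(rng.integers(0, 2))):
                clusters = []
                for slot in range(int(rng.integers(1, 4))):
                    base = 150 * slot + int(rng.integers(0, 60))
                    clusters.append(cluster(base, base + int(rng.integers(15, 60))))
                reps.append(clusters)
            groups = cluster_overlap(reps, cfg)
            for grp in groups:
                for i, x in enumerate(grp):
                    for y in grp[i + 1 :]:
                        assert min(x.end, y.end) - max(x.start, y.start) >= 10
            assert len(groups) == exhaustive_max(reps)


class TestGeneHitTable:
    def _fc(self, gene, family, site_type="7mer-m8"):
        c = cluster(100, 130, gene=gene)
        return fc(c, SeedMatch(gene, 5, 7, site_type, family))

    def test_two_replica_support_is_hit(self):
        reps = [
            [self._fc("g1", "famA")],
            [],
            [self._fc("g1", "famA")],
        ]
        table = gene_hit_table(reps, FilterConfig())
        row = table.iloc[0]
        assert row["hit"] and row["n_replicas"] == 2 and row["replicas"] == "0,2"

    def test_single_replica_not_hit(self):
        reps = [[self._fc("g1", "famA")], [], []]
        assert not gene_hit_table(reps, FilterConfig())["hit"].any()

    def test_gene_with_two_families_reports_both(self):
        reps = [
            [self._fc("g1", "famA"), self._fc("g1", "famB")],
            [self._fc("g1", "famA")],
        ]
        table = gene_hit_table(reps, FilterConfig()).set_index("family_id")
        assert bool(table.loc["famA", "hit"]) is True
        assert bool(table.loc["famB", "hit"]) is False

    def test_site_types_aggregated(self):
        reps = [
            [self._fc("g1", "famA", "8mer")],
            [self._fc("g1", "famA", "7mer-A1")],
        ]
        table = gene_hit_table(reps, FilterConfig())
        assert table.iloc[0]["site_types"] == "7mer-A1,8mer"
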