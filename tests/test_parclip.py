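import math
import random

import numpy as np
import pytest

from spongeclip.parclip import (
    AlignedRead,
    Mismatch,
    ParclipConfig,
    ParclipError,
    ReadGroup,
    annotate_clusters,
    apply_read_filters,
    call_all_clusters,
    call_clusters,
    group_reads,
    ingest_alignments,
    kde_signal,
    mutation_profile,
    read_alignments_sam,
    read_alignments_tsv,
    write_alignments_tsv,
)
from spongeclip.annotation import Region, RegionSet, SequenceStore


def make_read(start, length, strand="+", conv=(), other=(), t_pos=None, chrom="c"):
    mms = []
    for p in conv:
        mms.append(Mismatch(p, "T", "C") if strand == "+" else Mismatch(p, "A", "G"))
    for p, r, a in other:
        mms.append(Mismatch(p, r, a))
    mms.sort(key=lambda m: m.pos)
    return AlignedRead(chrom, strand, start, length, tuple(mms), t_pos)


def naive_kde(group, bandwidth):
    """Independent per-position double-loop density computation."""
    conv, nonconv = [], []
    for r in group.reads:
        cset = {
            mm.pos
            for mm in r.mismatches
            if (r.strand == "+" and mm.ref == "T" and mm.read == "C")
            or (r.strand == "-" and mm.ref == "A" and mm.read == "G")
        }
        conv.extend(sorted(cset))
        for t in r.t_positions or ():
            if r.start <= t < r.end and t not in cset:
                nonconv.append(t)

    def dens(events):
        out = []
        for p in range(group.start, group.end):
            s = 0.0
            for e in events:
                s += math.exp(-0.5 * ((p - e) / bandwidth) ** 2) / (
                    bandwidth * math.sqrt(2 * math.pi)
                )
            out.append(s / len(events) if events else 0.0)
        return out

    return dens(conv), dens(nonconv)


def random_group(rng):
    n = int(rng.integers(5, 15))
    strand = "+" if rng.random() < 0.5 else "-"
    reads = []
    cursor = 100
    for _ in range(n):
        start = cursor + int(rng.integers(0, 8))
        length = int(rng.integers(15, 31))
        covered = list(range(start, start + length))
        t_pos = sorted(rng.choice(covered, size=int(rng.integers(1, 8)), replace=False))
        conv = [p for p in t_pos if rng.random() < 0.4]
        reads.append(
            make_read(start, length, strand, conv=conv, t_pos=tuple(int(x) for x in t_pos))
        )
        cursor = start
    start = min(r.start for r in reads)
    end = max(r.end for r in reads)
    return ReadGroup("c", strand, start, end, reads)


class TestIngestFilters:
    def test_short_read_dropped(self):
        cfg = ParclipConfig()
        assert apply_read_filters([make_read(0, 12)], cfg) == []
        assert len(apply_read_filters([make_read(0, 13)], cfg)) == 1

    def test_non_conversion_mismatch_dropped(self):
        cfg = ParclipConfig()
        bad = make_read(0, 20, conv=(5,), other=((8, "G", "A"),))
        clean = make_read(0, 20, conv=(5,))
        assert apply_read_filters([bad, clean], cfg) == [clean]

    def test_minus_strand_conversion_is_genomic_a_to_g(self):
        cfg = ParclipConfig()
        read = make_read(0, 20, strand="-", conv=(5,))
        assert apply_read_filters([read], cfg) == [read]
        # genomic T>C on a minus-strand read is NOT a conversion
        bad = AlignedRead("c", "-", 0, 20, (Mismatch(5, "T", "C"),))
        assert apply_read_filters([bad], cfg) == []

    def test_tsv_roundtrip(self, tmp_path):
        reads = [
            make_read(10, 20, conv=(15,)),
            make_read(40, 25, strand="-", other=((50, "G", "T"),)),
            make_read(80, 18),
        ]
        p = tmp_path / "aln.tsv"
        write_alignments_tsv(reads, p)
        back = read_alignments_tsv(p)
        assert [(r.chrom, r.strand, r.start, r.read_len, r.mismatches) for r in back] == [
            (r.chrom, r.strand, r.start, r.read_len, r.mismatches) for r in reads
        ]

    def test_tsv_with_reference_fills_t_positions(self, tmp_path):
        ref = SequenceStore({"c": "AATTTACGAA" * 10})
        p = tmp_path / "aln.tsv"
        write_alignments_tsv([make_read(0, 10)], p)
        (r,) = read_alignments_tsv(p, reference=ref)
        assert r.t_positions == (2, 3, 4)


class TestSamIngest:
    REF20 = "AACGTACGTTACGTACGTAC"  # chr1[10:30]

    def _sam(self, tmp_path, flag, query, md, nm=1):
        text = (
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:100\n"
            f"r1\t{flag}\tchr1\t11\t42\t20M\t*\t0\t0\t{query}\t*\tNM:i:{nm}\tMD:Z:{md}\n"
        )
        p = tmp_path / "a.sam"
        p.write_text(text)
        return p

    def test_plus_strand_mismatch_recovered(self, tmp_path):
        query = self.REF20[:4] + "C" + self.REF20[5:]  # T->C at genomic 14
        p = self._sam(tmp_path, 0, query, "4T15")
        (r,) = read_alignments_sam(p)
        assert r.strand == "+" and r.start == 10 and r.read_len == 20
        assert r.mismatches == (Mismatch(14, "T", "C"),)
        assert 14 in r.t_positions

    def test_minus_strand_uses_genomic_bases(self, tmp_path):
        query = self.REF20[:1] + "G" + self.REF20[2:]  # A->G at genomic 11
        p = self._sam(tmp_path, 16, query, "1A18")
        (r,) = read_alignments_sam(p)
        assert r.strand == "-"
        assert r.mismatches == (Mismatch(11, "A", "G"),)
        assert 11 in r.t_positions  # genomic A is a sense-strand T on '-'

    def test_missing_md_advises_tsv(self, tmp_path):
        text = (
            "@SQ\tSN:chr1\tLN:100\n"
            f"r1\t0\tchr1\t11\t42\t20M\t*\t0\t0\t{self.REF20}\t*\n"
        )
        p = tmp_path / "a.sam"
        p.write_text(text)
        with pytest.raises(ParclipError, match="TSV"):
            read_alignments_sam(p)

    def test_ingest_dispatch_applies_filters(self, tmp_path):
        query = self.REF20[:4] + "C" + self.REF20[5:]
        p = self._sam(tmp_path, 0, query, "4T15")
        assert len(ingest_alignments(p, ParclipConfig())) == 1
        assert ingest_alignments(p, ParclipConfig(min_read_length=25)) == []


class TestMutationProfile:
    def test_all_tc(self):
        reads = [make_read(0, 20, conv=(i,)) for i in range(10)]
        prof = mutation_profile(reads)
        assert prof["T>C"] == 100.0

    def test_mixture_percentages(self):
        reads = [make_read(0, 20, conv=(5,)) for _ in range(7)]
        reads += [make_read(0, 20, other=((8, "G", "A"),)) for _ in range(3)]
        prof = mutation_profile(reads)
        assert prof["T>C"] == pytest.approx(70.0)
        assert prof["G>A"] == pytest.approx(30.0)
        assert sum(prof.values()) == pytest.approx(100.0)

    def test_minus_strand_complemented_to_read_orientation(self):
        (prof) = mutation_profile([make_read(0, 20, strand="-", conv=(5,))])
        assert prof["T>C"] == 100.0

    def test_empty_profile_all_zero(self):
        prof = mutation_profile([make_read(0, 20)])
        assert sum(prof.values()) == 0.0


class TestGroupReads:
    def test_four_stacked_reads_no_group(self):
        reads = [make_read(100, 20) for _ in range(4)]
        assert group_reads(reads, ParclipConfig()) == []

    def test_five_identical_reads_one_group(self):
        reads = [make_read(100, 20) for _ in range(5)]
        (g,) = group_reads(reads, ParclipConfig())
        assert (g.start, g.end) == (100, 120)

    def test_gap_separates_groups(self):
        reads = [make_read(100, 20) for _ in range(5)]
        reads += [make_read(200, 20) for _ in range(5)]
        assert len(group_reads(reads, ParclipConfig())) == 2

    def test_strands_not_chained(self):
        reads = [make_read(100, 20) for _ in range(5)]
        reads += [make_read(100, 20, strand="-") for _ in range(5)]
        assert len(group_reads(reads, ParclipConfig())) == 2


class TestKdeSignal:
    def test_single_conversion_peak_symmetric(self):
        reads = [make_read(100, 30, conv=(110,), t_pos=(110,)) for _ in range(5)]
        g = ReadGroup("c", "+", 100, 130, reads)
        pos, conv, _ = kde_signal(g, ParclipConfig())
        assert pos[int(np.argmax(conv))] == 110
        for d in range(1, 10):
            assert conv[10 - d] == pytest.approx(conv[10 + d])

    def test_all_converted_zero_nonconversion(self):
        reads = [make_read(100, 30, conv=(110,), t_pos=(110,)) for _ in range(5)]
        g = ReadGroup("c", "+", 100, 130, reads)
        _, _, nonconv = kde_signal(g, ParclipConfig())
        assert np.all(nonconv == 0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(17)
        cfg = ParclipConfig()
        for _ in range(100):
            g = random_group(rng)
            _, conv, nonconv = kde_signal(g, cfg)
            o_conv, o_nonconv = naive_kde(g, cfg.bandwidth)
            assert np.max(np.abs(conv - np.array(o_conv))) < 1e-9
            assert np.max(np.abs(nonconv - np.array(o_nonconv))) < 1e-9


class TestCallClusters:
    def test_single_site_cluster_mode(self):
        reads = [make_read(100, 30, conv=(110,), t_pos=(110,)) for _ in range(6)]
        g = ReadGroup("c", "+", 100, 130, reads)
        (c,) = call_clusters(g, ParclipConfig())
        assert c.mode_location == 110
        assert c.start <= 100 and c.end >= 130
        assert c.read_count == 6 and c.conversion_count == 6
        assert c.conversion_locations == (110,)

    def test_short_run_discarded_without_read_extension(self):
        t_pos = (104, 109, 110, 111, 115)
        reads = [make_read(100, 20, conv=(104,), t_pos=t_pos) for _ in range(6)]
        g = ReadGroup("c", "+", 100, 120, reads)
        assert call_clusters(g, ParclipConfig(extend_by_read=False)) == []
        (c,) = call_clusters(g, ParclipConfig(extend_by_read=True))
        assert (c.start, c.end) == (100, 120)

    def test_two_hotspots_two_clusters(self):
        middle_t = (126, 127, 128)
        reads = [
            make_read(100, 30, conv=(110,), t_pos=(110,) + middle_t) for _ in range(5)
        ] + [
            make_read(125, 30, conv=(140,), t_pos=middle_t + (140,)) for _ in range(5)
        ]
        (g,) = group_reads(reads, ParclipConfig())
        clusters = call_clusters(g, ParclipConfig())
        assert len(clusters) == 2
        assert [c.mode_location for c in clusters] == [110, 140]

    def test_no_conversions_no_clusters(self):
        reads = [make_read(100, 30, t_pos=(110,)) for _ in range(6)]
        g = ReadGroup("c", "+", 100, 130, reads)
        assert call_clusters(g, ParclipConfig()) == []

    def test_order_invariance(self):
        rng = np.random.default_rng(23)
        groups = [random_group(rng) for _ in range(20)]
        reads = [r for g in groups for r in g.reads]
        baseline = call_all_clusters(reads, ParclipConfig())
        shuffled = reads[:]
        random.Random(99).shuffle(shuffled)
        assert call_all_clusters(shuffled, ParclipConfig()) == baseline

    def test_emitted_clusters_satisfy_thresholds(self, small_sim):
        from spongeclip.simulate import make_annotation, plant_sites, simulate_parclip

        cfg = ParclipConfig()
        ann = make_annotation(small_sim)
        truth = plant_sites(small_sim, ann)
        reads = apply_read_filters(simulate_parclip(small_sim, ann, truth, 0), cfg)
        clusters = call_all_clusters(reads, cfg)
        assert clusters
        for c in clusters:
            assert c.end - c.start >= cfg.min_cluster_size
            assert c.read_count >= cfg.min_read_count_per_cluster
            assert len(c.conversion_locations) >= cfg.min_conversion_locations
            assert c.conversion_count >= cfg.min_conversion_count
            assert c.start <= c.mode_location < c.end
            assert all(c.start <= p < c.end for p in c.conversion_locations)


class TestAnnotateClusters:
    @pytest.fixture
    def regions(self):
        return RegionSet(
            [
                Region("g1", "t1", "c", 0, 100, "+", "CDS"),
                Region("g1", "t1", "c", 100, 200, "+", "3UTR"),
            ]
        )

    def _cluster(self, start, end):
        from spongeclip.parclip import Cluster

        return Cluster("c", "+", start, end, 6, 3, (start + 2,), start + 2)

    def test_fully_inside_3utr(self, regions):
        annotated, occ = annotate_clusters([self._cluster(120, 150)], regions)
        assert annotated[0].region_label == "3UTR"
        assert annotated[0].gene_id == "g1"
        assert occ == {"3UTR": 100.0}

    def test_straddling_maximal_overlap(self, regions):
        # 60% of the cluster lies in the 3'UTR
        (c,), occ = annotate_clusters([self._cluster(88, 118)], regions)
        assert c.region_label == "3UTR"

    def test_no_overlap_intergenic_and_occupancy_sums(self, regions):
        annotated, occ = annotate_clusters(
            [self._cluster(120, 150), self._cluster(500, 520)], regions
        )
        assert annotated[1].region_label == "intergenic"
        assert sum(occ.values()) == pytest.approx(100.0)


class TestConfig:
    def test_ini_roundtrip(self, tmp_path):
        cfg = ParclipConfig(bandwidth=4.0, min_cluster_size=12, extend_by_read=False)
        p = tmp_path / "params.ini"
        cfg.to_ini(p)
        assert ParclipConfig.from_ini(p) == cfg

    def test_unknown_key_lists_valid_keys(self, tmp_path):
        p = tmp_path / "params.ini"
        p.write_text("BANDWIDT=3\n")
        with pytest.raises(ParclipError, match="BANDWIDTH"):
            ParclipConfig.from_ini(p)

    def test_invalid_values_rejected(self):
        with pytest.raises(ParclipError):
            ParclipConfig(bandwidth=0)
        with pytest.raises(ParclipError):
            ParclipConfig(min_cluster_size=0)
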