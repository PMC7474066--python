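import numpy as np
import pytest

from camoscan import GenomicInterval, Reference
from camoscan.evaluate import (CORRECT, INCORRECT, UNMAPPED, DepthTrack,
                               call_camo_regions, classify_reads,
                               correctness_summary, depth_track,
                               read_length_rescue_table, CamoRegion)
from camoscan.intervals import Gene, Panel
from camoscan.mapping import AlignmentSet, GenomeIndex
from camoscan.simulate import ReadBatch
from conftest import random_reference


def _tiny_aset(index, placements, read_length=100):
    """Hand-built AlignmentSet: placements = list of (gpos, strand, mapq)
    per read, one pair per two entries."""
    n_pairs = len(placements) // 2
    names = [f"sim|i|1|chr1|0|0|+|{k}" for k in range(n_pairs)]
    seqs = np.zeros((n_pairs, read_length), dtype=np.uint8)
    aset = AlignmentSet(index, ReadBatch(read_length, names, seqs, seqs))
    for r, (gpos, strand, mapq) in enumerate(placements):
        aset.mapped[r] = gpos >= 0
        aset.gpos[r] = gpos
        aset.strand[r] = strand
        aset.mapq[r] = mapq
    return aset


@pytest.fixture(scope="module")
def flat_index():
    return GenomeIndex(random_reference(30_000, seed=21))


class TestClassify:
    def _aset_with_truth(self, index, truth, placements, read_length=100):
        n_pairs = len(placements) // 2
        names = [
            f"sim|i|1|chr1|{t[0]}|{t[1]}|{t[2]}|{k}"
            for k, t in enumerate(truth)
        ]
        seqs = np.zeros((n_pairs, read_length), dtype=np.uint8)
        aset = AlignmentSet(index,
                            ReadBatch(read_length, names, seqs, seqs))
        for r, (gpos, strand, mapq) in enumerate(placements):
            aset.mapped[r] = gpos >= 0
            aset.gpos[r] = gpos
            aset.strand[r] = strand
            aset.mapq[r] = mapq
        return aset

    def test_categories(self, flat_index):
        truth = [(1000, 1200, "+")]
        # read1: exact position; read2: mapped 2 kb away (wrong locus)
        aset = self._aset_with_truth(flat_index, truth,
                                     [(1000, 0, 60), (3200, 1, 27)])
        cats = classify_reads(aset)
        assert cats.tolist() == [CORRECT, INCORRECT]

    def test_low_mapq_counts_as_unmapped_even_at_true_position(self,
                                                               flat_index):
        truth = [(1000, 1200, "+")]
        aset = self._aset_with_truth(flat_index, truth,
                                     [(1000, 0, 5), (1200, 1, 60)])
        assert classify_reads(aset).tolist() == [UNMAPPED, CORRECT]

    def test_position_tolerance_inclusive(self, flat_index):
        truth = [(1000, 1200, "+")]
        aset = self._aset_with_truth(flat_index, truth,
                                     [(1020, 0, 60), (1221, 1, 60)])
        assert classify_reads(aset).tolist() == [CORRECT, INCORRECT]

    def test_wrong_strand_is_incorrect(self, flat_index):
        truth = [(1000, 1200, "+")]
        aset = self._aset_with_truth(flat_index, truth,
                                     [(1000, 1, 60), (1200, 1, 60)])
        assert classify_reads(aset).tolist() == [INCORRECT, CORRECT]

    def test_summary_percentages_recompute_from_counts(self, flat_index):
        truth = [(1000, 1200, "+"), (2000, 2200, "+")]
        aset = self._aset_with_truth(
            flat_index, truth,
            [(1000, 0, 60), (1200, 1, 60), (2000, 0, 3), (5000, 1, 40)],
        )
        cats = classify_reads(aset)
        summary = correctness_summary(cats, aset)
        by = summary.set_index("category")
        assert by.loc["correct", "count"] == 2
        assert by.loc["unmapped", "count"] == 1
        assert summary["count"].sum() == 4
        assert summary["percent"].sum() == pytest.approx(100.0)

    def test_counts_invariant_to_read_order(self, flat_index):
        truth = [(1000, 1200, "+"), (2000, 2200, "-")]
        placements = [(1000, 0, 60), (1200, 1, 60), (2000, 1, 60),
                      (2200, 0, 60)]
        aset = self._aset_with_truth(flat_index, truth, placements)
        c1 = np.sort(classify_reads(aset))
        truth2 = truth[::-1]
        placements2 = placements[2:] + placements[:2]
        aset2 = self._aset_with_truth(flat_index, truth2, placements2)
        assert np.array_equal(np.sort(classify_reads(aset2)), c1)


class TestDepth:
    def test_single_alignment_covers_exactly_its_span(self, flat_index):
        aset = _tiny_aset(flat_index, [(500, 0, 60), (-1, 0, 0)], 150)
        track = depth_track(aset, [GenomicInterval("chr1", 0, 2000)],
                            mq_min=10)
        vals = track.values["chr1"]
        assert vals[499] == 0 and vals[500] == 1 and vals[649] == 1 \
            and vals[650] == 0
        assert vals.sum() == 150

    def test_low_mapq_alignment_contributes_nowhere(self, flat_index):
        aset = _tiny_aset(flat_index, [(500, 0, 0), (-1, 0, 0)], 150)
        track = depth_track(aset, [GenomicInterval("chr1", 0, 2000)],
                            mq_min=10)
        assert track.values["chr1"].sum() == 0

    def test_half_overlapping_alignments_manual_pileup_oracle(self,
                                                              flat_index):
        aset = _tiny_aset(flat_index, [(500, 0, 60), (575, 1, 60)], 150)
        track = depth_track(aset, [GenomicInterval("chr1", 0, 2000)],
                            mq_min=10)
        vals = track.values["chr1"]
        assert np.all(vals[575:650] == 2)
        assert np.all(vals[500:575] == 1) and np.all(vals[650:725] == 1)


def _panel_one_gene(start=0, end=10_000):
    g = Gene("G1", GenomicInterval("chr1", start, end, "G1"),
             (GenomicInterval("chr1", start + 100, start + 300, "G1.ex1"),))
    return Panel((g,))


def _track(depths, regions):
    return DepthTrack(20, regions, {"chr1": np.asarray(depths, np.int32)})


class TestCamoRegions:
    def brute_force(self, depth, thr, merge, min_low, core):
        """Per-base set -> run -> merge oracle."""
        low = [i for i, d in enumerate(depth) if d < thr]
        if not low:
            return []
        groups = [[low[0], low[0] + 1]]
        for b in low[1:]:
            if b - groups[-1][1] <= merge:
                groups[-1][1] = b + 1
            else:
                groups.append([b, b + 1])
        out = []
        for s, e in groups:
            n_low = sum(1 for b in low if s <= b < e)
            if n_low >= min_low and min(depth[s:e]) <= core:
                out.append((s, e))
        return out

    def test_uniform_high_depth_yields_nothing(self):
        panel = _panel_one_gene(0, 500)
        track = _track([40] * 500, panel.gene_bodies())
        assert call_camo_regions(track, panel) == []

    def test_merge_boundary_at_50(self):
        depth = np.full(500, 40)
        depth[100:130] = 0
        depth[180:210] = 0   # gap exactly 50 -> merged
        panel = _panel_one_gene(0, 500)
        regions = call_camo_regions(_track(depth, panel.gene_bodies()), panel)
        assert [(r.interval.start, r.interval.end) for r in regions] \
            == [(100, 210)]

    def test_split_at_gap_51(self):
        depth = np.full(500, 40)
        depth[100:130] = 0
        depth[181:211] = 0   # gap 51 -> two regions
        panel = _panel_one_gene(0, 500)
        regions = call_camo_regions(_track(depth, panel.gene_bodies()), panel)
        assert [(r.interval.start, r.interval.end) for r in regions] \
            == [(100, 130), (181, 211)]

    def test_shallow_noise_dip_suppressed(self):
        depth = np.full(500, 40)
        depth[200:260] = 18  # many low bases but no core collapse
        panel = _panel_one_gene(0, 500)
        assert call_camo_regions(_track(depth, panel.gene_bodies()),
                                 panel) == []

    def test_agrees_with_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(22)
        panel = _panel_one_gene(0, 2000)
        for _ in range(25):
            depth = rng.integers(0, 45, size=2000)
            regions = call_camo_regions(_track(depth, panel.gene_bodies()),
                                        panel)
            oracle = self.brute_force(depth.tolist(), 20, 50, 20, 10)
            assert [(r.interval.start, r.interval.end) for r in regions] \
                == oracle

    def test_idempotent_under_recall(self):
        rng = np.random.default_rng(23)
        depth = rng.integers(0, 45, size=2000)
        panel = _panel_one_gene(0, 2000)
        track = _track(depth, panel.gene_bodies())
        first = call_camo_regions(track, panel)
        second = call_camo_regions(track, panel)
        assert [(r.interval.start, r.interval.end) for r in first] \
            == [(r.interval.start, r.interval.end) for r in second]

    def test_exonic_flag(self):
        depth = np.full(10_000, 40)
        depth[150:400] = 0     # overlaps the exon at 100-300
        depth[5000:5200] = 0   # intronic
        panel = _panel_one_gene(0, 10_000)
        regions = call_camo_regions(_track(depth, panel.gene_bodies()), panel)
        assert [r.exonic for r in regions] == [True, False]


class TestRescueTable:
    def _camo(self, gene):
        iv = GenomicInterval("chr1", 10, 60, gene)
        return CamoRegion(iv, gene, 2.0, 50, 10, 8, [], True)

    def test_classification_rules(self):
        g = [Gene(f"G{i}", GenomicInterval("chr1", i * 1000, i * 1000 + 900,
                                           f"G{i}"),
                  ()) for i in range(1, 4)]
        panel = Panel(tuple(g))
        camo = {
            70: [self._camo("G1"), self._camo("G2")],
            100: [self._camo("G1"), self._camo("G2")],
            150: [self._camo("G2")],
            250: [self._camo("G2")],
        }
        table = read_length_rescue_table(camo, panel).set_index("gene")
        assert table.loc["G1", "status"] == "rescued-by-longer"
        assert table.loc["G2", "status"] == "low-at-all-lengths"
        assert table.loc["G3", "status"] == "never-low"

    def test_missing_read_length_is_an_error(self):
        panel = Panel((Gene("G1", GenomicInterval("chr1", 0, 900, "G1"),
                            ()),))
        with pytest.raises(ValueError, match="250"):
            read_length_rescue_table({70: [], 100: [], 150: []}, panel)
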