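import numpy as np
import pandas as pd
import pytest

from camoscan import (GenomicInterval, Reference, compute_mappability,
                      exon_mean_mappability, filter_hits, flag_panel,
                      homology_search)
from camoscan.homology import HomologyHit, search_panel
from camoscan.intervals import Gene, Panel
from camoscan._seq import revcomp
from conftest import random_reference


def brute_force_mappability(ref: Reference, k: int) -> dict[str, np.ndarray]:
    """Independent oracle: dictionary count of every k-mer on both strands."""
    from collections import Counter

    counts: Counter = Counter()
    for name in ref.names:
        code = ref.contig(name)
        for arr in (code, revcomp(code)):
            for i in range(arr.size - k + 1):
                counts[arr[i:i + k].tobytes()] += 1
    out = {}
    for name in ref.names:
        code = ref.contig(name)
        track = np.zeros(max(0, code.size - k + 1), dtype=np.float32)
        for i in range(track.size):
            window = code[i:i + k]
            track[i] = 0.0 if (window >= 4).any() \
                else 1.0 / counts[window.tobytes()]
        out[name] = track
    return out


class TestMappability:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        code = rng.integers(0, 4, 3000).astype(np.uint8)
        code[1800:2100] = code[200:500]   # duplicated tract
        code[1000:1005] = 4               # hard-masked patch
        ref = Reference({"a": code[:2500], "b": code[2500:]})
        track = compute_mappability(ref, k=31)
        oracle = brute_force_mappability(ref, 31)
        for name in ref.names:
            np.testing.assert_allclose(track.values[name], oracle[name])

    def test_unique_sequence_scores_one(self):
        ref = random_reference(10_000, seed=12)
        track = compute_mappability(ref, k=75)
        assert float(track.values["chr1"].mean()) > 0.999

    def test_duplicated_tract_interior_scores_half(self):
        rng = np.random.default_rng(13)
        code = rng.integers(0, 4, 6000).astype(np.uint8)
        code[4000:4500] = code[1000:1500]
        track = compute_mappability(Reference({"c": code}), k=75)
        assert np.all(track.values["c"][1000:1426] == 0.5)
        assert np.all(track.values["c"][4000:4426] == 0.5)

    def test_three_copies_score_third(self):
        rng = np.random.default_rng(14)
        code = rng.integers(0, 4, 8000).astype(np.uint8)
        code[3000:3400] = code[1000:1400]
        code[6000:6400] = code[1000:1400]
        track = compute_mappability(Reference({"c": code}), k=75)
        assert np.all(np.isclose(track.values["c"][1000:1326], 1 / 3))

    def test_contig_shorter_than_k_empty_track(self):
        ref = Reference({"tiny": "ACGTACGT", "big": "ACGT" * 50})
        track = compute_mappability(ref, k=75)
        assert track.values["tiny"].size == 0


class TestExonMean:
    def _frame(self, track, iv):
        return exon_mean_mappability(track, {"G": [iv]})

    def test_unique_exon_not_flagged(self):
        ref = random_reference(5000, seed=15)
        track = compute_mappability(ref, k=75)
        row = self._frame(track, GenomicInterval("chr1", 100, 300)).iloc[0]
        assert row.mean_mappability == 1.0 and not row.flagged

    def test_two_copy_exon_mean_half_flagged_inclusive(self):
        rng = np.random.default_rng(16)
        code = rng.integers(0, 4, 6000).astype(np.uint8)
        code[4000:4600] = code[1000:1600]
        track = compute_mappability(Reference({"chr1": code}), k=75)
        row = self._frame(
            track, GenomicInterval("chr1", 1100, 1300)).iloc[0]
        assert row.mean_mappability == 0.5 and row.flagged  # <= rule

    def test_half_unique_exon_mean_computed_by_direct_average(self):
        """Oracle: the mean equals the hand-computed positional average."""
        rng = np.random.default_rng(17)
        code = rng.integers(0, 4, 6000).astype(np.uint8)
        code[4000:4800] = code[1000:1800]
        ref = Reference({"chr1": code})
        track = compute_mappability(ref, k=75)
        iv = GenomicInterval("chr1", 900, 1100)
        row = self._frame(track, iv).iloc[0]
        expected = float(track.values["chr1"][900:1100].mean())
        assert row.mean_mappability == pytest.approx(expected)
        assert 0.5 < row.mean_mappability < 1.0 and not row.flagged

    def test_exon_without_valid_positions_flagged(self):
        # the exon lies past the last position admitting a full k-mer
        ref = Reference({"chr1": "ACGT" * 25})
        track = compute_mappability(ref, k=75)
        row = self._frame(track, GenomicInterval("chr1", 40, 80)).iloc[0]
        assert np.isnan(row.mean_mappability) and row.flagged

    def test_hard_masked_exon_scores_zero_and_flagged(self):
        ref = Reference({"chr1": "N" * 200 + "ACGT" * 100})
        track = compute_mappability(ref, k=75)
        row = self._frame(track, GenomicInterval("chr1", 10, 80)).iloc[0]
        assert row.mean_mappability == 0.0 and row.flagged


class TestHomologySearch:
    def _planted(self, n_mismatch, seed=18, tract=200):
        rng = np.random.default_rng(seed)
        code = rng.integers(0, 4, 12_000).astype(np.uint8)
        copy = code[2000:2000 + tract].copy()
        if n_mismatch:
            # interior positions, well separated
            pos = np.linspace(15, tract - 15, n_mismatch).astype(int)
            copy[pos] = (copy[pos] + 1) % 4
        code[8000:8000 + tract] = copy
        return Reference({"chr1": code}), GenomicInterval("chr1", 2000,
                                                          2000 + tract)

    def test_unique_exon_yields_no_hits_after_self_exclusion(self):
        ref = random_reference(10_000, seed=19)
        hits = homology_search(GenomicInterval("chr1", 4000, 4400), ref)
        assert hits == []

    def test_planted_copy_mismatches_counted_exactly(self):
        ref, exon = self._planted(4)
        hits = homology_search(exon, ref)
        fwd = [h for h in hits if h.subject.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].mismatches == 4
        assert fwd[0].subject.start == 8000
        assert fwd[0].alignment_length >= 195

    def test_copy_with_eleven_mismatches_found_but_filtered(self):
        ref, exon = self._planted(11)
        hits = homology_search(exon, ref)
        fwd = [h for h in hits if h.subject.strand == "+"]
        assert len(fwd) == 1 and fwd[0].mismatches == 11
        assert filter_hits(fwd, exon_length=len(exon)) == []

    def test_short_exon_warns_and_returns_nothing(self):
        ref = random_reference(1000, seed=20)
        with pytest.warns(UserWarning, match="word size"):
            assert homology_search(GenomicInterval("chr1", 10, 18), ref) == []


class TestFilterAndFlag:
    def _hit(self, mismatches, length, exon_len=200):
        return HomologyHit(
            GenomicInterval("chr1", 0, exon_len),
            GenomicInterval("chr1", 5000, 5000 + length),
            length, mismatches,
        )

    @pytest.mark.parametrize(
        "mism,length,kept",
        [(10, 190, True), (10, 210, True), (11, 200, False),
         (0, 189, False), (0, 211, False), (0, 200, True)],
    )
    def test_inclusive_boundaries(self, mism, length, kept):
        hits = filter_hits([self._hit(mism, length)], exon_length=200)
        assert bool(hits) is kept

    def _panel(self):
        g1 = Gene("G1", GenomicInterval("c", 0, 1000, "G1"),
                  (GenomicInterval("c", 100, 300, "G1.ex1"),))
        g2 = Gene("G2", GenomicInterval("c", 2000, 3000, "G2"),
                  (GenomicInterval("c", 2100, 2300, "G2.ex1"),))
        return Panel((g1, g2))

    def test_union_rule(self):
        panel = self._panel()
        mapp = pd.DataFrame(
            [dict(gene="G1", flagged=True), dict(gene="G2", flagged=False)]
        )
        no_hits = pd.DataFrame(columns=["gene"])
        flags = flag_panel(panel, mapp, no_hits)
        assert flags.set_index("gene")["flagged"].to_dict() \
            == {"G1": True, "G2": False}
        hits = pd.DataFrame([dict(gene="G2")])
        flags2 = flag_panel(panel, mapp, hits)
        assert flags2["flagged"].all()

    def test_flagging_is_monotone_in_hits(self):
        """Adding a hit never unflags a gene."""
        panel = self._panel()
        mapp = pd.DataFrame(
            [dict(gene="G1", flagged=True), dict(gene="G2", flagged=False)]
        )
        base = flag_panel(panel, mapp, pd.DataFrame(columns=["gene"]))
        more = flag_panel(panel, mapp, pd.DataFrame([dict(gene="G1")]))
        before = base.set_index("gene")["flagged"]
        after = more.set_index("gene")["flagged"]
        assert (after | ~before).all()


class TestPanelRecovery:
    def test_camo_truth_recovered_with_no_false_cross_gene_hits(
            self, small_panel):
        """Every planted pairing with identity >= 0.95 and tract >= 200 bp
        is found; clean genes yield no surviving hits."""
        ref, panel, truth = small_panel
        hits = search_panel(panel, ref)
        camo_genes = {p.gene for p in truth}
        assert set(hits["gene"]) == camo_genes
        for pair in truth:
            sub = hits[hits.gene == pair.gene]
            hit_iv = GenomicInterval("chr1", int(sub.subject_start.min()),
                                     int(sub.subject_end.max()))
            assert hit_iv.overlaps(pair.pseudo_tract)
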