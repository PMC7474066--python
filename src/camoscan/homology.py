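"""Exon-level homology screening: k-mer mappability and seeded local search.

Two independent screens flag panel exons that short reads may not map
uniquely to:

* an alignability track: for every position, 1 / (number of exact genome
  occurrences of the k-mer starting there, counting both strands; default
  k = 75), averaged per buffered exon and flagged at mean <= 0.5;
* a seeded local-homology search of each buffered exon sequence against the
  whole genome (exact 11 bp words extended with x-drop), filtered to hits
  with <= 10 mismatches and an alignment length within 10 bp of the query.

A gene is flagged when ANY of its exons trips either screen (union
semantics — the conservative choice for a screening panel). Mappability
counts exact k-mer occurrences: at the sequence identities where
camouflage occurs (>= 97%) homologous tracts still share exact 75-mers.
Extension is substitution-only (match +1, mismatch -4, x-drop 50) because
no indel divergence is modelled anywhere in the pipeline; the ``gaps``
field of a hit is therefore always 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import _seq
from .intervals import GenomicInterval, Panel
from .reference import Reference


@dataclass
class MappabilityTrack:
    """Per-contig arrays of 1/occurrence-count for each full-k-mer position.

    Positions whose k-mer contains N score 0; contigs shorter than k get an
    empty track.
    """

    k: int
    values: dict[str, np.ndarray]

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        track = self.values[iv.contig]
        return track[iv.start:min(iv.end, track.size)]


def compute_mappability(reference: Reference, k: int = 75) -> MappabilityTrack:
    """Alignability of every position: 1 / #exact occurrences (both strands)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    fwd_views = {}
    all_windows = []
    for name in reference.names:
        code = reference.contig(name)
        if code.size < k:
            fwd_views[name] = None
            continue
        fwd = np.ascontiguousarray(sliding_window_view(code, k))
        rev = np.ascontiguousarray(sliding_window_view(_seq.revcomp(code), k))
        fwd_views[name] = fwd
        all_windows.append(fwd)
        all_windows.append(rev)
    if not all_windows:
        return MappabilityTrack(k, {n: np.zeros(0, np.float32)
                                    for n in reference.names})
    stacked = np.concatenate(all_windows).view(f"S{k}").ravel()
    uniq, counts = np.unique(stacked, return_counts=True)

    values: dict[str, np.ndarray] = {}
    for name in reference.names:
        fwd = fwd_views[name]
        if fwd is None:
            values[name] = np.zeros(0, dtype=np.float32)
            continue
        keys = fwd.view(f"S{k}").ravel()
        occ = counts[np.searchsorted(uniq, keys)]
        track = (1.0 / occ).astype(np.float32)
        code = reference.contig(name)
        bad = np.concatenate([[0], np.cumsum((code >= 4).astype(np.int64))])
        track[(bad[k:] - bad[:-k]) > 0] = 0.0
        values[name] = track
    return MappabilityTrack(k, values)


def exon_mean_mappability(
    track: MappabilityTrack, buffered_exons: dict[str, list[GenomicInterval]],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Mean mappability per (buffered, merged) exon with a <=threshold flag.

    Exons with no position admitting a full k-mer get an undefined mean and
    are flagged (conservative).
    """
    rows = []
    for gene, exons in buffered_exons.items():
        for ex in exons:
            vals = track.slice(ex)
            if vals.size == 0:
                mean, flagged = float("nan"), True
            else:
                mean = float(vals.mean())
                flagged = mean <= threshold
            rows.append(
                dict(gene=gene, contig=ex.contig, start=ex.start, end=ex.end,
                     mean_mappability=mean, flagged=flagged)
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HomologyHit:
    """A local alignment of an exon query to another genomic location."""

    query: GenomicInterval
    subject: GenomicInterval
    alignment_length: int
    mismatches: int
    gaps: int = 0
    subject_class: str = ""

    def __post_init__(self):
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.mismatches > self.alignment_length:
            raise ValueError("mismatches exceed alignment length")


def _xdrop_extend(query: np.ndarray, subject: np.ndarray, qpos: int,
                  spos: int, word: int, xdrop: int,
                  match: int = 1, mismatch: int = 4):
    """Ungapped two-sided x-drop extension from an exact word match.

    Returns (qstart, qend, sstart, send, mismatches) of the best-scoring
    extension, half-open in both sequences.
    """
    # right extension (starting after the seed word)
    score = word * match
    best = score
    best_right = qpos + word
    q, s = qpos + word, spos + word
    while q < query.size and s < subject.size:
        if query[q] == subject[s] and query[q] < 4:
            score += match
        else:
            score -= mismatch
        q += 1
        s += 1
        if score > best:
            best, best_right = score, q
        if score <= best - xdrop:
            break
    # left extension
    score = best
    best_left = qpos
    q, s = qpos - 1, spos - 1
    while q >= 0 and s >= 0:
        if query[q] == subject[s] and query[q] < 4:
            score += match
        else:
            score -= mismatch
        if score > best:
            best, best_left = score, q
        if score <= best - xdrop:
            break
        q -= 1
        s -= 1
    qstart, qend = best_left, best_right
    sstart = spos - (qpos - qstart)
    send = spos + (qend - qpos)
    seg_q = query[qstart:qend]
    seg_s = subject[sstart:send]
    mism = int(np.count_nonzero((seg_q != seg_s) | (seg_q >= 4)))
    return qstart, qend, sstart, send, mism


def homology_search(
    exon: GenomicInterval, reference: Reference, word_size: int = 11,
    xdrop: int = 50, min_length: int = 30,
) -> list[HomologyHit]:
    """Seeded local search of one exon sequence against the whole genome.

    Exact ``word_size`` matches on both strands are extended without gaps
    under x-drop; the self-hit (identical coordinates) is excluded;
    overlapping extensions of the same locus are deduplicated. Hits shorter
    than ``min_length`` (chance word matches) are dropped.
    """
    query = reference.fetch(exon)
    if query.size < word_size:
        import warnings

        warnings.warn(f"exon {exon} shorter than word size; no hits")
        return []
    index = _word_index(reference, word_size)
    hits: dict[tuple, HomologyHit] = {}
    for strand, q in (("+", query), ("-", _seq.revcomp(query))):
        vals, valid = _word_values(q, word_size)
        covered: dict[int, list[tuple[int, int]]] = {}
        for qpos in range(vals.size):
            if not valid[qpos]:
                continue
            lo = np.searchsorted(index.svals, vals[qpos], "left")
            hi = np.searchsorted(index.svals, vals[qpos], "right")
            for gpos in index.spos[lo:hi]:
                diag = int(gpos) - qpos
                spans = covered.get(diag)
                if spans and any(qs <= qpos < qe for qs, qe in spans):
                    continue
                qs, qe, ss, se, mism = _xdrop_extend(
                    q, index.genome, qpos, int(gpos), word_size, xdrop
                )
                covered.setdefault(diag, []).append((qs, qe))
                if qe - qs < min_length:
                    continue
                contig, local = index.to_local(ss)
                subject = GenomicInterval(contig, local, local + (qe - qs),
                                          strand=strand)
                if (strand == "+" and subject.contig == exon.contig
                        and subject.start == exon.start + qs
                        and subject.end == exon.start + qe):
                    continue  # self-hit
                key = (strand, contig, subject.start, subject.end)
                prev = hits.get(key)
                if prev is None or mism < prev.mismatches:
                    hits[key] = HomologyHit(exon, subject, qe - qs, mism)
    return sorted(hits.values(),
                  key=lambda h: (h.subject.contig, h.subject.start,
                                 h.subject.strand))


_word_cache: dict = {}


def _word_index(reference: Reference, word_size: int):
    from .mapping import GenomeIndex

    key = (id(reference), word_size)
    idx = _word_cache.get(key)
    if idx is None:
        idx = GenomeIndex(reference, word_size)
        _word_cache.clear()
        _word_cache[key] = idx
    return idx


def _word_values(code: np.ndarray, k: int):
    from .mapping import _kmer_values

    return _kmer_values(code, k)


def filter_hits(hits: Sequence[HomologyHit], exon_length: int,
                max_mismatch: int = 10, max_len_diff: int = 10
                ) -> list[HomologyHit]:
    """Keep hits with <= max_mismatch mismatches and an alignment length
    within max_len_diff of the query exon length (inclusive bounds)."""
    return [
        h for h in hits
        if h.mismatches <= max_mismatch
        and abs(h.alignment_length - exon_length) <= max_len_diff
    ]


def search_panel(
    panel: Panel, reference: Reference, word_size: int = 11,
    max_mismatch: int = 10, max_len_diff: int = 10,
) -> pd.DataFrame:
    """Filtered homology hits for every buffered exon of the panel."""
    buffered = panel.buffered_exons(reference.lengths)
    rows = []
    for gene, exons in buffered.items():
        for ex in exons:
            hits = homology_search(ex, reference, word_size)
            for h in filter_hits(hits, len(ex), max_mismatch, max_len_diff):
                rows.append(
                    dict(gene=gene, query_contig=ex.contig,
                         query_start=ex.start, query_end=ex.end,
                         subject_contig=h.subject.contig,
                         subject_start=h.subject.start,
                         subject_end=h.subject.end,
                         subject_strand=h.subject.strand,
                         alignment_length=h.alignment_length,
                         mismatches=h.mismatches, gaps=h.gaps)
                )
    cols = ["gene", "query_contig", "query_start", "query_end",
            "subject_contig", "subject_start", "subject_end",
            "subject_strand", "alignment_length", "mismatches", "gaps"]
    return pd.DataFrame(rows, columns=cols)


def flag_panel(panel: Panel, exon_mappability: pd.DataFrame,
               hits: pd.DataFrame) -> pd.DataFrame:
    """Union rule: a gene is flagged iff any exon is mappability-flagged OR
    has at least one surviving homology hit."""
    mapp_flagged = set(
        exon_mappability.loc[exon_mappability["flagged"], "gene"]
    )
    hit_flagged = set(hits["gene"]) if len(hits) else set()
    rows = []
    for g in panel.genes:
        rows.append(
            dict(gene=g.name,
                 mappability_flag=g.name in mapp_flagged,
                 homology_flag=g.name in hit_flagged,
                 flagged=g.name in mapp_flagged or g.name in hit_flagged)
        )
    return pd.DataFrame(rows)


def low_complexity_mask(reference: Reference, window: int = 64,
                        max_entropy: float = 1.0) -> list[GenomicInterval]:
    """Optional window-entropy low-complexity screen (off by default).

    Windows whose per-base Shannon entropy over ACGT falls below
    ``max_entropy`` bits are reported for masking before homology search.
    """
    out = []
    for name in reference.names:
        code = reference.contig(name)
        for start in range(0, max(0, code.size - window + 1), window):
            seg = code[start:start + window]
            counts = np.bincount(seg[seg < 4], minlength=4)
            tot = counts.sum()
            if tot == 0:
                continue
            p = counts[counts > 0] / tot
            if -(p * np.log2(p)).sum() < max_entropy:
                out.append(GenomicInterval(name, start, start + window))
    from .intervals import merge_intervals

    return merge_intervals(out)
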