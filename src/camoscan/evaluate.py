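"""Mapping evaluation: truth classification, filtered depth, camo regions.

Reads carry their true origin in their names, so every alignment can be
scored correct / incorrect / unmapped: alignments with MAPQ below a cutoff
(default 10) count as unmapped because such reads are routinely filtered
from downstream analyses; a mapped read is correct when it lands on the
true contig and strand within a small positional tolerance.

Camouflaged regions are maximal runs of bases whose MAPQ-filtered depth
falls below a threshold (default 20 at MAPQ >= 20), merged when separated
by at most 50 bp, and annotated with read counts, the number of non-unique
(MAPQ < 10) reads, the alternate loci those reads could have mapped to, and
whether the region intersects an exon. Regions supported by fewer than
``min_low_bases`` sub-threshold bases are suppressed: at 40X combined
coverage, isolated sub-threshold bases arise from sampling noise at a rate
of about 1e-4 per base, whereas homology-driven camouflage produces
hundreds of contiguous low bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Panel, merge_intervals
from .mapping import AlignmentSet
from .simulate import parse_read_name

CORRECT, INCORRECT, UNMAPPED = 0, 1, 2
_CATEGORY = {CORRECT: "correct", INCORRECT: "incorrect", UNMAPPED: "unmapped"}


def classify_reads(aset: AlignmentSet, mq_unmapped: int = 10,
                   pos_tolerance: int = 20) -> np.ndarray:
    """Per-read category (CORRECT/INCORRECT/UNMAPPED) against encoded truth."""
    idx = aset.index
    n = aset.n_reads
    true_gpos = np.empty(n, dtype=np.int64)
    true_strand = np.empty(n, dtype=np.int8)
    for p, name in enumerate(aset.names):
        t = parse_read_name(name)
        goff = idx.to_global(t.contig, 0)
        true_gpos[2 * p] = goff + t.pos1
        true_gpos[2 * p + 1] = goff + t.pos2
        s1 = 0 if t.strand1 == "+" else 1
        true_strand[2 * p] = s1
        true_strand[2 * p + 1] = 1 - s1
    same_contig = aset.index.contig_index(aset.gpos) == \
        aset.index.contig_index(true_gpos)
    ok = (
        aset.mapped
        & (aset.mapq >= mq_unmapped)
        & same_contig
        & (aset.strand == true_strand)
        & (np.abs(aset.gpos - true_gpos) <= pos_tolerance)
    )
    out = np.full(n, INCORRECT, dtype=np.int8)
    out[ok] = CORRECT
    out[~aset.mapped | (aset.mapq < mq_unmapped)] = UNMAPPED
    return out


def correctness_summary(categories: np.ndarray, aset: AlignmentSet,
                        label: str = "all", read_length: int | None = None,
                        mq_unmapped: int = 10) -> pd.DataFrame:
    """Counts and percentages of correct/incorrect/unmapped reads."""
    total = categories.size
    rows = []
    counts = {name: int(np.count_nonzero(categories == cat))
              for cat, name in _CATEGORY.items()}
    for name, cnt in counts.items():
        rows.append(
            dict(label=label,
                 read_length=read_length or aset.read_length,
                 mq_threshold=mq_unmapped, category=name, count=cnt,
                 percent=100.0 * cnt / total if total else float("nan"))
        )
    return pd.DataFrame(rows)


def summaries_by_population(categories: np.ndarray, aset: AlignmentSet,
                            populations: dict[str, str],
                            mq_unmapped: int = 10) -> pd.DataFrame:
    """Per-population correctness (individuals mapped via ``populations``)."""
    per_read_pop = np.empty(aset.n_reads, dtype=object)
    for p, name in enumerate(aset.names):
        pop = populations[parse_read_name(name).individual]
        per_read_pop[2 * p] = pop
        per_read_pop[2 * p + 1] = pop
    frames = []
    for pop in sorted(set(populations.values())):
        sel = per_read_pop == pop
        frames.append(
            correctness_summary(categories[sel], aset, label=pop,
                                mq_unmapped=mq_unmapped)
        )
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------------ depth

@dataclass
class DepthTrack:
    """Per-contig MAPQ-filtered read depth, evaluated over given regions."""

    mq_min: int
    regions: list[GenomicInterval]
    values: dict[str, np.ndarray]

    def region_values(self, iv: GenomicInterval) -> np.ndarray:
        return self.values[iv.contig][iv.start:iv.end]

    def mean_depth(self) -> float:
        """Mean over all evaluated region bases (zeros included)."""
        total, n = 0.0, 0
        for iv in merge_intervals(self.regions):
            vals = self.region_values(iv)
            total += float(vals.sum())
            n += vals.size
        return total / n if n else float("nan")


def depth_track(aset: AlignmentSet, regions: list[GenomicInterval],
                mq_min: int = 10) -> DepthTrack:
    """Per-base count of alignments with MAPQ >= mq_min covering each base.

    Every base of every region is represented, zeros included.
    """
    idx = aset.index
    values = {name: np.zeros(idx.reference.lengths[name], dtype=np.int32)
              for name in idx.names}
    keep = aset.mapped & (aset.mapq >= mq_min)
    gpos = aset.gpos[keep]
    L = aset.read_length
    diff = np.zeros(idx.size + 1, dtype=np.int32)
    np.add.at(diff, gpos, 1)
    np.add.at(diff, gpos + L, -1)
    global_depth = np.cumsum(diff[:-1])
    for name, off in zip(idx.names, idx.starts):
        clen = idx.reference.lengths[name]
        values[name][:] = global_depth[off:off + clen]
    return DepthTrack(mq_min, list(regions), values)


# ----------------------------------------------------------- camo regions

@dataclass
class CamoRegion:
    """A merged low-depth interval with its diagnostic annotation."""

    interval: GenomicInterval
    gene: str
    mean_depth: float
    n_low_bases: int
    n_reads: int
    n_nonunique: int
    alt_locations: list[GenomicInterval]
    exonic: bool


def _low_runs(low: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True values."""
    padded = np.concatenate([[False], low, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def call_camo_regions(
    track: DepthTrack, panel: Panel, aset: AlignmentSet | None = None,
    depth_threshold: int = 20, merge_distance: int = 50,
    min_low_bases: int = 20, core_depth_max: int | None = None,
    mq_nonunique: int = 10,
    annotation: list[GenomicInterval] | None = None,
) -> list[CamoRegion]:
    """Camouflaged regions: depth < threshold, merged within 50 bp.

    Called over gene bodies only (the flanks exist to keep coverage uniform
    at gene boundaries, and their own boundaries taper by construction).
    ``annotation`` intervals (e.g. known pseudogene tracts) label alternate
    mapping locations.

    Two noise guards separate camouflage from binomial sampling dips, which
    at 40X graze the threshold at ~1e-4 per base: a region must contain at
    least ``min_low_bases`` sub-threshold bases, and its minimum depth must
    reach ``core_depth_max`` (default threshold // 2). Ambiguity-trapped
    cores lose unique mapping entirely (depth near 0), whereas a 40X
    binomial fluctuation essentially never reaches half the threshold.
    """
    if core_depth_max is None:
        core_depth_max = depth_threshold // 2
    exons = panel.all_exons()
    out: list[CamoRegion] = []
    for gene_iv in panel.gene_bodies():
        depth = track.region_values(gene_iv)
        low = depth < depth_threshold
        runs = _low_runs(low)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_distance:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            n_low = int(np.count_nonzero(low[s:e]))
            if n_low < min_low_bases:
                continue
            if int(depth[s:e].min()) > core_depth_max:
                continue
            iv = GenomicInterval(gene_iv.contig, gene_iv.start + s,
                                 gene_iv.start + e, gene_iv.name)
            mean_depth = float(depth[s:e].mean())
            n_reads = n_nonuniq = 0
            alt: list[GenomicInterval] = []
            if aset is not None:
                g0 = aset.index.to_global(iv.contig, iv.start)
                g1 = aset.index.to_global(iv.contig, iv.end)
                reads = aset.reads_overlapping(g0, g1)
                n_reads = int(reads.size)
                nonuniq = reads[aset.mapq[reads] < mq_nonunique]
                n_nonuniq = int(nonuniq.size)
                alt_pos = aset.alt_gpos[nonuniq]
                alt_pos = np.unique(alt_pos[alt_pos >= 0])
                alt = _label_alt_locations(
                    alt_pos, aset, annotation or [], panel
                )
            out.append(
                CamoRegion(iv, gene_iv.name, mean_depth, n_low, n_reads,
                           n_nonuniq, alt,
                           exonic=any(iv.overlaps(ex) for ex in exons))
            )
    return out


def _label_alt_locations(alt_gpos: np.ndarray, aset: AlignmentSet,
                         annotation: list[GenomicInterval], panel: Panel
                         ) -> list[GenomicInterval]:
    L = aset.read_length
    spans = []
    for g in alt_gpos.tolist():
        contig, pos = aset.index.to_local(int(g))
        label = "intergenic"
        probe = GenomicInterval(contig, pos, pos + L)
        for ann in annotation:
            if probe.overlaps(ann):
                label = ann.name or "annotated"
                break
        else:
            for gene_iv in panel.gene_bodies():
                if probe.overlaps(gene_iv):
                    label = gene_iv.name
                    break
        spans.append(GenomicInterval(contig, pos, pos + L, label))
    return merge_intervals(spans)


def camo_regions_to_frame(regions: list[CamoRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            dict(contig=r.interval.contig, start=r.interval.start,
                 end=r.interval.end, gene=r.gene,
                 mean_depth=round(r.mean_depth, 3),
                 n_low_bases=r.n_low_bases, n_reads=r.n_reads,
                 n_nonunique=r.n_nonunique, exonic=r.exonic,
                 alt_locations=";".join(
                     f"{a.contig}:{a.start}-{a.end}({a.name})"
                     for a in r.alt_locations))
        )
    cols = ["contig", "start", "end", "gene", "mean_depth", "n_low_bases",
            "n_reads", "n_nonunique", "exonic", "alt_locations"]
    return pd.DataFrame(rows, columns=cols)


def write_camo_bed(path, regions: list[CamoRegion]) -> None:
    """BED6 with score = mean depth x 10, rounded."""
    from .formats import write_bed

    ivs = [r.interval for r in regions]
    scores = [round(r.mean_depth * 10) for r in regions]
    write_bed(path, ivs, scores=scores)


# -------------------------------------------------- read-length behaviour

NEVER_LOW = "never-low"
RESCUED = "rescued-by-longer"
LOW_AT_ALL = "low-at-all-lengths"
MIXED = "mixed"


def read_length_rescue_table(
    camo_by_length: dict[int, list[CamoRegion]], panel: Panel,
    required_lengths: tuple[int, ...] = (70, 100, 150, 250),
) -> pd.DataFrame:
    """Gene-wise camouflage status across read lengths.

    A gene is low-at-all-lengths iff it has a camo region at every read
    length; rescued iff low at some shorter length and clean at the
    longest.
    """
    for rl in required_lengths:
        if rl not in camo_by_length:
            raise ValueError(f"camo calls for read length {rl} are missing")
    lengths = sorted(required_lengths)
    low: dict[str, set[int]] = {g.name: set() for g in panel.genes}
    for rl in lengths:
        for region in camo_by_length[rl]:
            low[region.gene].add(rl)
    rows = []
    for g in panel.genes:
        at = low[g.name]
        if not at:
            status = NEVER_LOW
        elif len(at) == len(lengths):
            status = LOW_AT_ALL
        elif lengths[-1] not in at:
            status = RESCUED
        else:
            status = MIXED
        rows.append(
            dict(gene=g.name, status=status,
                 low_at=",".join(str(rl) for rl in sorted(at)))
        )
    return pd.DataFrame(rows)
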