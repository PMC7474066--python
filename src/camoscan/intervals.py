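"""Genomic intervals, interval algebra and gene panels.

All coordinates in this package are 0-based half-open; conversion to the
1-based conventions of SAM/VCF happens only in :mod:`camoscan.formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a contig."""

    contig: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self):
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return replace(
            self, start=max(self.start, other.start), end=min(self.end, other.end)
        )

    def pad(self, left: int, right: int | None = None,
            contig_length: int | None = None) -> "GenomicInterval":
        """Expand by ``left``/``right`` bp, clipped at 0 and contig length."""
        if right is None:
            right = left
        start = max(0, self.start - left)
        end = self.end + right
        if contig_length is not None:
            end = min(end, contig_length)
        return replace(self, start=start, end=end)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, joining any two separated by <= ``gap`` bp.

    Names of merged members are joined with ';' (deduplicated, order kept).
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.contig, i.start, i.end)):
        if out and out[-1].contig == iv.contig and iv.start - out[-1].end <= gap:
            prev = out[-1]
            names = [n for n in prev.name.split(";") if n]
            if iv.name and iv.name not in names:
                names.append(iv.name)
            out[-1] = replace(
                prev, end=max(prev.end, iv.end), name=";".join(names)
            )
        else:
            out.append(iv)
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


@dataclass(frozen=True)
class Gene:
    """A panel gene: the gene body plus its (sorted, non-overlapping) exons."""

    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        for ex in self.exons:
            if not self.interval.contains(ex):
                raise ValueError(f"exon {ex} outside gene {self.name}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"exons of {self.name} overlap or are unsorted")


@dataclass(frozen=True)
class Panel:
    """A gene panel with per-exon buffers and per-gene simulation flanks.

    ``buffer`` bp are added up- and downstream of each exon when computing
    the exon footprint used for mappability and homology screening;
    ``flank`` bp are added around each gene body to delimit the regions
    reads are simulated from, so coverage is uniform at gene boundaries.
    """

    genes: tuple[Gene, ...]
    buffer: int = 70
    flank: int = 2000

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def buffered_exons(
        self, contig_lengths: dict[str, int]
    ) -> dict[str, list[GenomicInterval]]:
        """Per-gene exons expanded by ``buffer`` bp, clipped and merged."""
        out: dict[str, list[GenomicInterval]] = {}
        for g in self.genes:
            clen = contig_lengths[g.interval.contig]
            padded = [ex.pad(self.buffer, contig_length=clen) for ex in g.exons]
            out[g.name] = merge_intervals(padded)
        return out

    def simulation_regions(
        self, contig_lengths: dict[str, int]
    ) -> list[GenomicInterval]:
        """Gene bodies padded by ``flank`` bp (read-simulation regions)."""
        return [
            g.interval.pad(self.flank, contig_length=contig_lengths[g.interval.contig])
            for g in self.genes
        ]

    def gene_bodies(self) -> list[GenomicInterval]:
        return [replace(g.interval, name=g.name) for g in self.genes]

    def all_exons(self) -> list[GenomicInterval]:
        return [ex for g in self.genes for ex in g.exons]
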