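"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA (60-column wrap), FASTQ (Phred+33), BED3/BED6, a biallelic-SNV subset
of VCF v4.2, and SAM v1.6. Internal coordinates are 0-based half-open;
the 1-based conventions of VCF and SAM are converted exactly here and
nowhere else. Writers emit canonical records such that write(read(x)) is
byte-identical for files this package produces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .intervals import GenomicInterval


class ParseError(ValueError):
    """Malformed record; message names the offending line number."""

    def __init__(self, path, line_no: int, msg: str):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """(name, uppercase sequence) pairs, in file order."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- FASTQ

def read_fastq(path) -> list[tuple[str, str, str]]:
    """(name, sequence, quality) triples."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise ParseError(path, len(lines), "FASTQ record truncated")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise ParseError(path, i + 1, "expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(path, i + 3, "expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(path, i + 4, "sequence/quality length mismatch")
        out.append((head[1:], seq, qual))
    return out


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ------------------------------------------------------------------ BED

def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6 -> intervals (BED is already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(path, ln, "BED line has fewer than 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ParseError(path, ln, "non-integer BED coordinates") from None
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            try:
                out.append(GenomicInterval(f[0], start, end, name, strand))
            except ValueError as e:
                raise ParseError(path, ln, str(e)) from None
    return out


def write_bed(path, intervals: Sequence[GenomicInterval],
              scores: Sequence[float] | None = None) -> None:
    """BED6 when any interval carries a name/strand or scores given, else BED3."""
    bed6 = scores is not None or any(iv.name or iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if bed6:
                score = 0 if scores is None else scores[i]
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


# ------------------------------------------------------------------ VCF

@dataclass(frozen=True)
class VcfRecord:
    """One biallelic SNV with a single-sample genotype.

    ``pos`` is 0-based internally; serialized POS is ``pos + 1``.
    ``gt`` is the slashed genotype string (``0/1``, ``1/1``, ``0/0/1/1``...).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    gt: str
    id: str = "."
    qual: str = "."
    filter: str = "PASS"
    info: str = "."

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only SNVs are supported")
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")

    @property
    def dosage(self) -> int:
        return sum(int(a) for a in self.gt.split("/"))


def read_vcf(path) -> tuple[list[VcfRecord], str]:
    """Parse a single-sample SNV VCF -> (records, sample name)."""
    records: list[VcfRecord] = []
    sample = "SAMPLE"
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) >= 10:
                    sample = cols[9]
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(path, ln, "VCF line has no sample column")
            try:
                pos = int(f[1]) - 1
            except ValueError:
                raise ParseError(path, ln, "non-integer POS") from None
            fmt = f[8].split(":")
            try:
                gt = f[9].split(":")[fmt.index("GT")].replace("|", "/")
            except ValueError:
                raise ParseError(path, ln, "FORMAT lacks GT") from None
            try:
                records.append(
                    VcfRecord(f[0], pos, f[3], f[4], gt, f[2], f[5], f[6], f[7])
                )
            except ValueError as e:
                raise ParseError(path, ln, str(e)) from None
    return records, sample


def write_vcf(path, records: Sequence[VcfRecord],
              contig_lengths: dict[str, int], sample: str = "SAMPLE") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=camoscan\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in sorted(records, key=lambda r: (r.contig, r.pos)):
            fh.write(
                f"{r.contig}\t{r.pos + 1}\t{r.id}\t{r.ref}\t{r.alt}\t{r.qual}"
                f"\t{r.filter}\t{r.info}\tGT\t{r.gt}\n"
            )


# ------------------------------------------------------------------ SAM

# FLAG bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class SamRecord:
    """One SAM alignment line. ``pos`` is 0-based internally (POS = pos+1)."""

    qname: str
    flag: int
    rname: str = "*"
    pos: int = -1
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = -1
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: tuple[str, ...] = ()

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    def reference_length(self) -> int:
        """Reference bases consumed by the CIGAR."""
        return sum(
            int(n) for n, op in _CIGAR_RE.findall(self.cigar) if op in "MDN=X"
        )

    def to_line(self) -> str:
        fields = [
            self.qname, str(self.flag), self.rname, str(self.pos + 1),
            str(self.mapq), self.cigar, self.rnext, str(self.pnext + 1),
            str(self.tlen), self.seq, self.qual, *self.tags,
        ]
        return "\t".join(fields)


def sam_header(contig_lengths: dict[str, int],
               program: str | None = None) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in contig_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    if program:
        lines.append(f"@PG\tID:camoscan\tPN:camoscan\tCL:{program}")
    return lines


def write_sam(path, records: Iterable[SamRecord],
              contig_lengths: dict[str, int], program: str | None = None) -> None:
    with open(path, "w") as fh:
        for line in sam_header(contig_lengths, program):
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_sam(path) -> tuple[list[SamRecord], dict[str, int]]:
    """Parse SAM -> (records, contig lengths from @SQ)."""
    records: list[SamRecord] = []
    contigs: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    kv = dict(
                        f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                    )
                    contigs[kv["SN"]] = int(kv["LN"])
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ParseError(path, ln, "SAM line has fewer than 11 fields")
            try:
                records.append(
                    SamRecord(
                        qname=f[0], flag=int(f[1]), rname=f[2], pos=int(f[3]) - 1,
                        mapq=int(f[4]), cigar=f[5], rnext=f[6], pnext=int(f[7]) - 1,
                        tlen=int(f[8]), seq=f[9], qual=f[10], tags=tuple(f[11:]),
                    )
                )
            except ValueError:
                raise ParseError(path, ln, "malformed SAM fields") from None
    return records, contigs
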