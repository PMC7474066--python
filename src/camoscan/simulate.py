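"""Diploid consensus construction and truth-labelled paired-end read simulation.

Per-individual diploid references are built the way a consensus caller
would: heterozygous SNVs become IUPAC ambiguity codes, which are then split
into two haplotype FASTAs (the alphabetically first base always goes to
haplotype 1). Reads are simulated per haplotype at a fixed expected depth
with a fragment model of ``2 * read_length + inner_distance`` where the
inner distance is Normal(mean, sd) truncated at zero, uniform fragment
placement wholly inside each region, Bernoulli(1/2) read-1 strand, and
i.i.d. substitution errors. No indels, mutations or quality profiles are
simulated. Every read name encodes its true origin losslessly so mapping
accuracy can be scored later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _seq
from .formats import VcfRecord, read_fastq, write_fastq
from .intervals import GenomicInterval
from .reference import Reference

#: Constant base quality written to FASTQ (Phred+33 'I' = Q40). The
#: downstream evaluation never consumes base qualities beyond caller input.
QUAL_CHAR = "I"


@dataclass(frozen=True)
class SimulationConfig:
    read_length: int = 150
    inner_distance_mean: float = 50.0
    inner_distance_sd: float = 10.0
    per_haplotype_coverage: float = 20.0
    error_rate: float = 0.0024
    max_n_per_read: int = 5
    flank: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.read_length <= 0 or self.per_haplotype_coverage <= 0:
            raise ValueError("read length and coverage must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error rate must be in [0, 1)")

    @property
    def mean_fragment(self) -> float:
        return 2 * self.read_length + self.inner_distance_mean


# ------------------------------------------------------------- consensus

def build_consensus(reference: Reference, records: list[VcfRecord]) -> dict[str, str]:
    """IUPAC consensus per contig: hom-alt replaced, het coded ambiguously."""
    seqs = {name: bytearray(_seq.decode(reference.contig(name)), "ascii")
            for name in reference.names}
    for rec in records:
        seq = seqs[rec.contig]
        ref_base = chr(seq[rec.pos])
        if ref_base != rec.ref:
            raise ValueError(
                f"VCF REF {rec.ref} != reference base {ref_base} at "
                f"{rec.contig}:{rec.pos + 1}"
            )
        if rec.dosage == len(rec.gt.split("/")):  # hom alt
            seq[rec.pos] = ord(rec.alt)
        elif rec.dosage > 0:  # het
            seq[rec.pos] = ord(_seq.IUPAC_HET[frozenset((rec.ref, rec.alt))])
    return {name: bytes(seq).decode("ascii") for name, seq in seqs.items()}


_SPLIT1 = np.full(256, 255, dtype=np.uint8)
_SPLIT2 = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _SPLIT1[ord(_b)] = _i
    _SPLIT2[ord(_b)] = _i
for _code, (_b1, _b2) in _seq.HET_BASES.items():
    _SPLIT1[ord(_code)] = "ACGT".index(_b1)
    _SPLIT2[ord(_code)] = "ACGT".index(_b2)


def split_haplotypes(consensus: dict[str, str]) -> tuple[Reference, Reference]:
    """Resolve biallelic IUPAC codes into two haplotype references.

    The alphabetically first base of each ambiguity code goes to haplotype 1.
    'N' (hard-masked reference) passes through to both haplotypes; three- or
    four-fold ambiguity codes are rejected since only biallelic SNVs are
    modelled.
    """
    hap1: dict[str, np.ndarray] = {}
    hap2: dict[str, np.ndarray] = {}
    for name, seq in consensus.items():
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        h1 = _SPLIT1[raw]
        if np.any(h1 == 255):
            bad = int(np.nonzero(h1 == 255)[0][0])
            raise ValueError(
                f"non-biallelic ambiguity code {seq[bad]!r} at {name}:{bad + 1}"
            )
        hap1[name] = h1
        hap2[name] = _SPLIT2[raw]
    return Reference(hap1), Reference(hap2)


# ------------------------------------------------------------ truth names

@dataclass(frozen=True)
class ReadTruth:
    """Decoded true origin of a simulated read pair."""

    individual: str
    haplotype: int
    contig: str
    pos1: int  # leftmost reference coordinate of read 1
    pos2: int  # leftmost reference coordinate of read 2
    strand1: str
    serial: int

    @property
    def strand2(self) -> str:
        return "-" if self.strand1 == "+" else "+"

    def encode(self) -> str:
        return (
            f"sim|{self.individual}|{self.haplotype}|{self.contig}"
            f"|{self.pos1}|{self.pos2}|{self.strand1}|{self.serial}"
        )


def parse_read_name(name: str) -> ReadTruth:
    fields = name.split("|")
    if len(fields) != 8 or fields[0] != "sim":
        raise ValueError(f"not a simulation truth name: {name!r}")
    return ReadTruth(
        individual=fields[1], haplotype=int(fields[2]), contig=fields[3],
        pos1=int(fields[4]), pos2=int(fields[5]), strand1=fields[6],
        serial=int(fields[7]),
    )


# -------------------------------------------------------------- read sets

@dataclass
class ReadBatch:
    """Paired reads held as code matrices, truth encoded in ``names``."""

    read_length: int
    names: list[str]
    seq1: np.ndarray  # (n_pairs, read_length) uint8
    seq2: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.names)

    def truths(self) -> list[ReadTruth]:
        return [parse_read_name(n) for n in self.names]

    @staticmethod
    def concat(batches: list["ReadBatch"]) -> "ReadBatch":
        if not batches:
            raise ValueError("no batches to concatenate")
        rl = batches[0].read_length
        if any(b.read_length != rl for b in batches):
            raise ValueError("mixed read lengths")
        return ReadBatch(
            rl,
            [n for b in batches for n in b.names],
            np.concatenate([b.seq1 for b in batches]),
            np.concatenate([b.seq2 for b in batches]),
        )

    def truth_frame(self):
        """Truth table mirroring the read names, one row per pair."""
        import pandas as pd

        return pd.DataFrame(
            [dict(name=n, individual=t.individual, haplotype=t.haplotype,
                  contig=t.contig, pos1=t.pos1, pos2=t.pos2,
                  strand1=t.strand1, serial=t.serial)
             for n, t in zip(self.names, self.truths())]
        )

    def write_truth_table(self, path) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)

    def write_fastq(self, prefix) -> tuple[str, str]:
        qual = QUAL_CHAR * self.read_length
        p1, p2 = f"{prefix}_R1.fastq", f"{prefix}_R2.fastq"
        write_fastq(
            p1, ((n, _seq.decode(s), qual) for n, s in zip(self.names, self.seq1))
        )
        write_fastq(
            p2, ((n, _seq.decode(s), qual) for n, s in zip(self.names, self.seq2))
        )
        return p1, p2

    @staticmethod
    def read_fastq_pair(path1, path2) -> "ReadBatch":
        rec1, rec2 = read_fastq(path1), read_fastq(path2)
        if [r[0] for r in rec1] != [r[0] for r in rec2]:
            raise ValueError("R1/R2 name mismatch")
        rl = len(rec1[0][1])
        return ReadBatch(
            rl,
            [r[0] for r in rec1],
            np.array([_seq.encode(r[1]) for r in rec1]),
            np.array([_seq.encode(r[1]) for r in rec2]),
        )


def _extract(code: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    return code[starts[:, None] + np.arange(length)]


def _revcomp_rows(rows: np.ndarray) -> np.ndarray:
    flipped = rows[:, ::-1]
    return np.where(flipped < 4, 3 - flipped, np.uint8(4)).astype(np.uint8)


def simulate_reads(
    hap1: Reference,
    hap2: Reference,
    regions: list[GenomicInterval],
    config: SimulationConfig,
    individual: str = "ind",
    rng: np.random.Generator | None = None,
) -> ReadBatch:
    """Simulate paired-end reads from both haplotypes over the regions.

    Expected combined depth over each region is
    ``2 * per_haplotype_coverage`` (pairs per haplotype = coverage x
    region_length / (2 x read_length), fragments wholly inside the region).
    Reads with more than ``max_n_per_read`` N bases are discarded and
    redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rl = config.read_length
    max_frag = int(2 * rl + config.inner_distance_mean
                   + 5 * config.inner_distance_sd)
    batches: list[ReadBatch] = []
    serial = 0

    for region in regions:
        if len(region) < max_frag:
            warnings.warn(
                f"region {region.contig}:{region.start}-{region.end} shorter "
                f"than maximum fragment ({max_frag} bp); skipped"
            )
            continue
        for hap_no, hap in ((1, hap1), (2, hap2)):
            code = hap.contig(region.contig)
            n_pairs = round(
                config.per_haplotype_coverage * len(region) / (2 * rl)
            )
            names: list[str] = [""] * n_pairs
            seq1 = np.empty((n_pairs, rl), dtype=np.uint8)
            seq2 = np.empty((n_pairs, rl), dtype=np.uint8)
            pending = np.arange(n_pairs)
            for _attempt in range(100):
                n = pending.size
                if n == 0:
                    break
                inner = np.maximum(
                    0,
                    np.rint(rng.normal(config.inner_distance_mean,
                                       config.inner_distance_sd, n)),
                ).astype(np.int64)
                frag = 2 * rl + inner
                starts = region.start + (
                    rng.random(n) * (len(region) - frag + 1)
                ).astype(np.int64)
                fwd_first = rng.random(n) < 0.5
                left = _extract(code, starts, rl)
                right = _extract(code, starts + frag - rl, rl)
                r_left, r_right = left.copy(), right.copy()
                if config.error_rate > 0:
                    for block in (r_left, r_right):
                        err = (rng.random(block.shape) < config.error_rate) & (
                            block < 4
                        )
                        shift = rng.integers(
                            1, 4, size=block.shape
                        ).astype(np.uint8)
                        block[err] = (block[err] + shift[err]) % 4
                s1 = np.where(fwd_first[:, None], r_left, _revcomp_rows(r_right))
                s2 = np.where(fwd_first[:, None], _revcomp_rows(r_right), r_left)
                ok = (
                    (np.count_nonzero(s1 >= 4, axis=1) <= config.max_n_per_read)
                    & (np.count_nonzero(s2 >= 4, axis=1) <= config.max_n_per_read)
                )
                rows = pending[ok]
                seq1[rows] = s1[ok]
                seq2[rows] = s2[ok]
                right_start = starts + frag - rl
                for j in np.nonzero(ok)[0]:
                    row = pending[j]
                    if fwd_first[j]:
                        truth = ReadTruth(
                            individual, hap_no, region.contig,
                            int(starts[j]), int(right_start[j]), "+",
                            serial + int(row),
                        )
                    else:
                        truth = ReadTruth(
                            individual, hap_no, region.contig,
                            int(right_start[j]), int(starts[j]), "-",
                            serial + int(row),
                        )
                    names[row] = truth.encode()
                pending = pending[~ok]
            else:
                raise RuntimeError(
                    "could not draw reads satisfying the N limit; is the "
                    "region mostly hard-masked?"
                )
            serial += n_pairs
            batches.append(ReadBatch(rl, names, seq1, seq2))

    if not batches:
        raise ValueError("no region was long enough to simulate from")
    return ReadBatch.concat(batches)


def simulate_individual(
    reference: Reference,
    records: list[VcfRecord],
    regions: list[GenomicInterval],
    config: SimulationConfig,
    individual: str = "ind",
) -> ReadBatch:
    """Consensus -> haplotype split -> paired-read simulation for one sample."""
    consensus = build_consensus(reference, records)
    hap1, hap2 = split_haplotypes(consensus)
    return simulate_reads(hap1, hap2, regions, config, individual=individual)


def make_variant_readset(
    reference: Reference,
    variant_records: list[VcfRecord],
    regions: list[GenomicInterval],
    config: SimulationConfig,
    individual: str = "variant",
) -> ReadBatch:
    """Read set for a planted-variant scenario.

    Heterozygous variants are handled by simulating each haplotype
    separately at half the combined coverage, which yields 50% alternate
    reads at the site in expectation — equivalent to post-editing half of
    the reads in the FASTQ.
    """
    for rec in variant_records:
        inside = any(
            r.contig == rec.contig and r.start <= rec.pos < r.end
            for r in regions
        )
        if not inside:
            raise ValueError(
                f"variant at {rec.contig}:{rec.pos + 1} outside simulated regions"
            )
    return simulate_individual(
        reference, variant_records, regions, config, individual=individual
    )
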