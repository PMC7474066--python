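"""In-memory reference genome with hard-masking support."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from . import _seq
from .intervals import GenomicInterval


class Reference:
    """Ordered mapping of contig name -> encoded uppercase sequence.

    Lowercase (soft-masked) bases are uppercased on load; only 'N' is
    treated as hard-masked, and :meth:`mask` only ever writes 'N'.
    """

    def __init__(self, contigs: Mapping[str, np.ndarray | str]):
        self._contigs: dict[str, np.ndarray] = {}
        for name, seq in contigs.items():
            code = _seq.encode(seq) if isinstance(seq, str) else np.asarray(
                seq, dtype=np.uint8
            )
            if code.size == 0:
                raise ValueError(f"contig {name!r} is empty")
            self._contigs[name] = code

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: int(c.size) for n, c in self._contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def contig(self, name: str) -> np.ndarray:
        return self._contigs[name]

    def fetch(self, iv: GenomicInterval) -> np.ndarray:
        """Encoded sequence for an interval; bounds-checked."""
        code = self._contigs[iv.contig]
        if iv.end > code.size:
            raise IndexError(
                f"{iv.contig}:{iv.start}-{iv.end} exceeds contig length {code.size}"
            )
        return code[iv.start:iv.end]

    def fetch_str(self, iv: GenomicInterval) -> str:
        return _seq.decode(self.fetch(iv))

    def mask(self, intervals: Iterable[GenomicInterval], flank: int = 0) -> "Reference":
        """New reference with the intervals (plus ``flank`` bp) set to N."""
        out = {n: c.copy() for n, c in self._contigs.items()}
        for iv in intervals:
            code = out[iv.contig]
            start = max(0, iv.start - flank)
            end = min(code.size, iv.end + flank)
            code[start:end] = _seq.N
        return Reference(out)

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        from .formats import read_fasta

        return cls(dict(read_fasta(path)))

    def to_fasta(self, path) -> None:
        from .formats import write_fasta

        write_fasta(path, [(n, _seq.decode(c)) for n, c in self._contigs.items()])
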