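"""Random-access genome sequence helpers (1-based inclusive coordinates)."""

from __future__ import annotations

from pyfaidx import Fasta

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Genome:
    """Thin pyfaidx wrapper exposing 1-based inclusive fetches."""

    def __init__(self, path: str) -> None:
        self._fa = Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive, forward strand.

        Raises KeyError for an unknown chromosome and ValueError when the
        interval runs off either end of the sequence.
        """
        if start < 1 or end > self.length(chrom):
            raise ValueError(
                f"{chrom}:{start}-{end} outside sequence of length {self.length(chrom)}"
            )
        return self._fa[chrom][start - 1 : end].seq

    def fetch_stranded(self, chrom: str, start: int, end: int, strand: str) -> str:
        s = self.fetch(chrom, start, end)
        return revcomp(s) if strand == "-" else s
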