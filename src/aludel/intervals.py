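"""Genomic intervals: the coordinate backbone of the package.

Internally every position is 0-based, half-open (``[start, end)``); all file
formats that use 1-based inclusive coordinates (RepeatMasker ``.out``, HGVS,
TSV exports) convert at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["GenomicInterval"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval on a named sequence.

    Parameters
    ----------
    seq_id:
        Name of the sequence the interval lives on.
    start, end:
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand:
        ``'+'`` or ``'-'``.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive convention."""
        return self.start + 1, self.end

    @classmethod
    def from_1based(
        cls, seq_id: str, start1: int, end1: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (as printed in files)."""
        return cls(seq_id, start1 - 1, end1, strand)

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)
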