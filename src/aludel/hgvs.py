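"""HGVS-style deletion descriptions and cDNA/genomic coordinate arithmetic.

Handles the two description flavours used for large gene deletions:

* genomic: ``REF:g.<start>_<end>del[<n>]`` (1-based inclusive), and
* cDNA with signed intronic offsets: ``c.<pos>[<+/-off>]_<pos>[<+/-off>]del[<n>]``
  (e.g. a whole-exon deletion described from the flanking introns).

Length suffixes are validated against the implied span and inconsistencies
are reported, never silently corrected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .intervals import GenomicInterval

__all__ = [
    "HgvsParseError",
    "GenomicDeletion",
    "CDnaDeletion",
    "Exon",
    "ExonMap",
    "to_hgvs_g",
    "parse_hgvs_g",
    "parse_hgvs_c",
    "c_deletion_length",
    "read_exon_map_tsv",
]


class HgvsParseError(ValueError):
    """Malformed or internally impossible HGVS description."""


@dataclass(frozen=True)
class GenomicDeletion:
    """Parsed ``g.`` deletion; coordinates 1-based inclusive."""

    ref_name: str
    start: int
    end: int
    stated_length: Optional[int]

    @property
    def implied_length(self) -> int:
        return self.end - self.start + 1

    @property
    def consistent(self) -> bool:
        """True when the length suffix (if any) matches the coordinate span."""
        return self.stated_length is None or self.stated_length == self.implied_length


_G_RE = re.compile(r"^(?P<ref>[^:\s]+):g\.(?P<s>\d+)_(?P<e>\d+)del(?P<n>\d+)?$")


def to_hgvs_g(ref_name: str, start: int, end: int, length: Optional[int] = None) -> str:
    """Format a genomic deletion description (1-based inclusive coordinates)."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    suffix = str(length) if length is not None else ""
    return f"{ref_name}:g.{start}_{end}del{suffix}"


def parse_hgvs_g(text: str) -> GenomicDeletion:
    """Parse ``REF:g.<start>_<end>del[<n>]``; inverse of :func:`to_hgvs_g`."""
    m = _G_RE.match(text.strip())
    if m is None:
        raise HgvsParseError(f"not a g. deletion description: {text!r}")
    start, end = int(m.group("s")), int(m.group("e"))
    if start > end:
        raise HgvsParseError(f"start {start} > end {end} in {text!r}")
    n = m.group("n")
    return GenomicDeletion(m.group("ref"), start, end, int(n) if n else None)


@dataclass(frozen=True)
class CDnaDeletion:
    """Parsed ``c.`` deletion with signed intronic offsets.

    Offsets are 0 when an endpoint is exonic; ``c.1370-2567`` has
    ``start_exon_pos=1370, start_offset=-2567``.
    """

    start_exon_pos: int
    start_offset: int
    end_exon_pos: int
    end_offset: int
    stated_length: Optional[int] = None
    ref_name: Optional[str] = None


_C_RE = re.compile(
    r"^(?:(?P<ref>[^:\s]+):)?c\."
    r"(?P<s>\d+)(?P<so>[+-]\d+)?_(?P<e>\d+)(?P<eo>[+-]\d+)?del(?P<n>\d+)?$"
)


def parse_hgvs_c(text: str) -> CDnaDeletion:
    """Parse ``[REF:]c.<pos>[±off]_<pos>[±off]del[<n>]``."""
    m = _C_RE.match(text.strip())
    if m is None:
        raise HgvsParseError(f"not a c. deletion description: {text!r}")
    n = m.group("n")
    return CDnaDeletion(
        start_exon_pos=int(m.group("s")),
        start_offset=int(m.group("so") or 0),
        end_exon_pos=int(m.group("e")),
        end_offset=int(m.group("eo") or 0),
        stated_length=int(n) if n else None,
        ref_name=m.group("ref"),
    )


@dataclass(frozen=True)
class Exon:
    """One exon: its cDNA span (1-based inclusive) and genomic placement."""

    cdna_start: int
    cdna_end: int
    genomic: GenomicInterval

    def __post_init__(self) -> None:
        if self.cdna_end - self.cdna_start + 1 != self.genomic.length():
            raise ValueError(
                f"exon c.{self.cdna_start}-{self.cdna_end} spans "
                f"{self.cdna_end - self.cdna_start + 1} bases but its genomic "
                f"interval spans {self.genomic.length()}"
            )


class ExonMap:
    """Ordered exon structure of a transcript on a genomic reference.

    Exons must be non-overlapping and their cDNA coordinates contiguous
    (``end_i + 1 == start_{i+1}``). ``strand`` is the coding strand on the
    genomic reference.
    """

    def __init__(self, exons: Sequence[Exon], strand: str = "+") -> None:
        if not exons:
            raise ValueError("exon map needs at least one exon")
        if strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exons = sorted(exons, key=lambda e: e.cdna_start)
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.cdna_start != prev.cdna_end + 1:
                raise ValueError(
                    f"cDNA coordinates not contiguous: exon ends at c.{prev.cdna_end}, "
                    f"next starts at c.{nxt.cdna_start}"
                )
            if prev.genomic.overlaps(nxt.genomic):
                raise ValueError("exon genomic intervals overlap")
        self.exons = tuple(exons)
        self.strand = strand

    def resolve(self, cdna_pos: int, offset: int = 0) -> int:
        """Genomic 1-based position of ``c.<cdna_pos><offset>``."""
        for e in self.exons:
            if e.cdna_start <= cdna_pos <= e.cdna_end:
                within = cdna_pos - e.cdna_start
                g1, g2 = e.genomic.to_1based()
                if self.strand == "+":
                    return g1 + within + offset
                return g2 - within - offset
        raise HgvsParseError(f"c.{cdna_pos} outside transcript (cDNA 1-"
                             f"{self.exons[-1].cdna_end})")


def c_deletion_length(d: CDnaDeletion, exons: ExonMap) -> int:
    """Genomic span (bp) of a deletion described in cDNA+offset coordinates.

    Both endpoints are resolved to genomic positions through the exon map and
    the signed intronic offsets; the result is ``|g_end - g_start| + 1``. For
    a single fully deleted exon spanning c.s-c.e with upstream offset u and
    downstream offset v this reduces to ``u + (e - s + 1) + v``.
    """
    g_start = exons.resolve(d.start_exon_pos, d.start_offset)
    g_end = exons.resolve(d.end_exon_pos, d.end_offset)
    lo, hi = sorted((g_start, g_end))
    if lo < 1:
        raise HgvsParseError("resolved endpoint falls before the reference start")
    return hi - lo + 1


def read_exon_map_tsv(path, strand: str = "+") -> ExonMap:
    """Read an exon map from TSV: exon_index, cdna_start, cdna_end, g_start, g_end.

    Genomic columns are 1-based inclusive; lines starting with '#' skipped.
    """
    exons = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, cs, ce, gs, ge = line.split("\t")[:5]
            exons.append(
                Exon(int(cs), int(ce), GenomicInterval.from_1based("ref", int(gs), int(ge)))
            )
    return ExonMap(exons, strand=strand)
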