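"""Deletion-junction mapping and microhomology resolution.

Given a wild-type reference and a mutant (junction) sequence that spans a
single contiguous deletion, the mapper anchors the two junction ends in the
reference with unique exact k-mer seeds, extends each anchor base-by-base to
its last matching nucleotide, and reads the deletion off the two maximal
extensions. When the deletion flanks share sequence (microhomology, typical
of Alu-Alu recombination junctions) the breakpoint is only defined up to a
slide window; the window is reported in full and the canonical placement is
the most-3' one, following the HGVS normalization rule.

All operations are deterministic string arithmetic: no heuristic aligner is
involved, which at single-locus scale reproduces exactly the manual
"last nucleotide showing identity between wild-type and mutant" procedure
used when reading Sanger traces of a junction amplicon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

from .intervals import GenomicInterval
from .repeats import RepeatPair

__all__ = [
    "DeletionCall",
    "JunctionMappingError",
    "AmbiguousAnchorError",
    "NoDeletionError",
    "InconsistentJunctionError",
    "map_deletion_junction",
    "microhomology_length",
    "normalize_3prime",
    "placement_window",
    "apply_deletion",
    "deletion_call",
    "call_to_vcf",
]

_VALID = frozenset("ACGT")


class JunctionMappingError(ValueError):
    """Base class for junction-mapping failures."""


class AmbiguousAnchorError(JunctionMappingError):
    """A junction-end k-mer is absent from, or repeated in, the reference."""


class NoDeletionError(JunctionMappingError):
    """The junction is consistent with the reference without any deletion."""


class InconsistentJunctionError(JunctionMappingError):
    """The junction cannot be explained by a single contiguous deletion."""


@dataclass(frozen=True)
class DeletionCall:
    """A mapped deletion with its microhomology/ambiguity structure.

    ``deletion`` is the canonical (most-3') placement. ``ambiguity`` is the
    interval of equivalent left-breakpoint start positions: it always covers
    exactly ``mh_len + 1`` placements, each of which removes the same mutant
    sequence from the reference.
    """

    ref_name: str
    deletion: GenomicInterval
    length: int
    mh_len: int
    ambiguity: GenomicInterval
    hgvs_g: str
    mechanism_hint: Optional[RepeatPair] = None

    def __post_init__(self) -> None:
        if self.length != self.deletion.length():
            raise ValueError("length must equal deletion interval length")
        if self.ambiguity.length() != self.mh_len + 1:
            raise ValueError("ambiguity window must cover mh_len + 1 placements")

    def to_json(self) -> str:
        d = {
            "ref_name": self.ref_name,
            "start_1based": self.deletion.start + 1,
            "end_1based": self.deletion.end,
            "length": self.length,
            "mh_len": self.mh_len,
            "ambiguity_start_1based": self.ambiguity.start + 1,
            "ambiguity_end_1based": self.ambiguity.end,
            "hgvs_g": self.hgvs_g,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _eq(x: str, y: str) -> bool:
    # non-ACGT characters never match (they terminate extensions/slides)
    return x == y and x in _VALID


def _find_unique(hay: str, needle: str) -> int:
    first = hay.find(needle)
    if first < 0:
        raise AmbiguousAnchorError(f"anchor {needle[:12]}... not found in reference")
    if hay.find(needle, first + 1) >= 0:
        raise AmbiguousAnchorError(f"anchor {needle[:12]}... matches reference twice")
    return first


def placement_window(ref: str, start: int, end: int) -> tuple[int, int]:
    """Left/right bounds of equivalent left-breakpoint placements.

    Returns ``(lo, hi)`` such that deleting ``[s, s+len)`` for any
    ``s in [lo, hi]`` yields the same mutant sequence as deleting
    ``[start, end)``. ``hi - lo`` is the microhomology length.
    """
    ref = ref.upper()
    if not (0 <= start < end <= len(ref)):
        raise ValueError(f"deletion [{start}, {end}) out of bounds for ref of {len(ref)}")
    d = end - start
    lo = start
    while lo > 0 and _eq(ref[lo - 1], ref[lo - 1 + d]):
        lo -= 1
    hi = start
    while hi + d < len(ref) and _eq(ref[hi], ref[hi + d]):
        hi += 1
    return lo, hi


def microhomology_length(ref: str, deletion: GenomicInterval) -> int:
    """Microhomology (breakpoint-overlap) length of a deletion.

    The largest number of bases by which the deletion can slide while
    producing the same mutant sequence: right-slides (bases just inside the
    5' end equal bases just after the 3' end) plus left-slides, counted
    symmetrically. The deletion has ``mh_len + 1`` equivalent placements.
    """
    lo, hi = placement_window(ref, deletion.start, deletion.end)
    return hi - lo


def normalize_3prime(ref: str, deletion: GenomicInterval) -> GenomicInterval:
    """Most-3' equivalent placement of a deletion (HGVS convention).

    Idempotent; the mutant sequence is unchanged by the shift.
    """
    _, hi = placement_window(ref, deletion.start, deletion.end)
    d = deletion.length()
    return replace(deletion, start=hi, end=hi + d)


def apply_deletion(ref: str, deletion: GenomicInterval) -> str:
    """Reference with the deleted interval removed."""
    if not (0 <= deletion.start < deletion.end <= len(ref)):
        raise ValueError("deletion out of bounds")
    return ref[: deletion.start] + ref[deletion.end :]


def deletion_call(
    ref: str,
    start: int,
    end: int,
    ref_name: str = "ref",
    mechanism_hint: Optional[RepeatPair] = None,
) -> DeletionCall:
    """Build a normalized :class:`DeletionCall` from a known deletion interval."""
    from .hgvs import to_hgvs_g

    lo, hi = placement_window(ref, start, end)
    d = end - start
    norm = GenomicInterval(ref_name, hi, hi + d)
    return DeletionCall(
        ref_name=ref_name,
        deletion=norm,
        length=d,
        mh_len=hi - lo,
        ambiguity=GenomicInterval(ref_name, lo, hi + 1),
        hgvs_g=to_hgvs_g(ref_name, hi + 1, hi + d, d),
        mechanism_hint=mechanism_hint,
    )


def map_deletion_junction(
    ref: str,
    junction: str,
    anchor_k: int = 25,
    ref_name: str = "ref",
    max_mismatches: int = 0,
) -> DeletionCall:
    """Map a single contiguous deletion from a junction (mutant) sequence.

    The junction must carry at least ``anchor_k`` deletion-free bases on each
    side of the breakpoint. Its first and last ``anchor_k``-mers are located
    in the reference (each must match exactly once); the left anchor is
    extended rightwards and the right anchor leftwards to the last matching
    nucleotide. The gap between the two maximal extensions on the reference
    is the deletion; their overlap on the junction is the microhomology.

    ``max_mismatches`` > 0 enables an error-tolerant extension mode for noisy
    junction reads: each extension may step over that many isolated
    mismatches. This changes microhomology semantics (a sequencing error
    inside the homology block shortens the reported overlap in exact mode and
    may lengthen it in tolerant mode), so the default is exact.

    Raises
    ------
    AmbiguousAnchorError
        If an end k-mer is missing from or repeated in the reference.
    NoDeletionError
        If the extensions imply a deletion of length <= 0.
    InconsistentJunctionError
        If junction bases remain unexplained by a single contiguous deletion.
    """
    ref_u = ref.upper()
    jn = junction.upper()
    n = len(jn)
    if n < 2 * anchor_k:
        raise JunctionMappingError(
            f"junction of {n} bp is shorter than two {anchor_k} bp anchors"
        )
    p = _find_unique(ref_u, jn[:anchor_k])
    right_pos = _find_unique(ref_u, jn[-anchor_k:])
    r_end = right_pos + anchor_k

    # extend the left anchor rightwards along ref/junction in lockstep
    L = anchor_k
    budget = max_mismatches
    while L < n and p + L < len(ref_u):
        if _eq(ref_u[p + L], jn[L]):
            L += 1
        elif budget > 0:
            budget -= 1
            L += 1
        else:
            break
    # extend the right anchor leftwards
    R = anchor_k
    budget = max_mismatches
    while R < n and r_end - R > 0:
        if _eq(ref_u[r_end - R - 1], jn[n - R - 1]):
            R += 1
        elif budget > 0:
            budget -= 1
            R += 1
        else:
            break

    if L + R < n:
        raise InconsistentJunctionError(
            f"{n - L - R} junction bases match neither flank extension; "
            "not a single contiguous deletion"
        )
    d = (r_end - p) - n
    if d <= 0:
        raise NoDeletionError("junction is explained by the reference without a deletion")

    # leftmost placement implied by the mapping, then the full ref-based window
    s0 = p + (n - R)
    return deletion_call(ref, s0, s0 + d, ref_name=ref_name)


def call_to_vcf(call: DeletionCall, ref: str) -> str:
    """Minimal VCF 4.2 symbolic-deletion record for a :class:`DeletionCall`.

    POS is the base before the deletion (1-based), END the last deleted base,
    HOMLEN the microhomology length — bit-identical to the JSON export.
    """
    pos1 = call.deletion.start  # 0-based start == 1-based position of base before
    if pos1 < 1:
        raise ValueError("deletion at reference start cannot be anchored in VCF")
    anchor_base = ref.upper()[pos1 - 1]
    header = (
        "##fileformat=VCFv4.2\n"
        '##ALT=<ID=DEL,Description="Deletion">\n'
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">\n'
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n'
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">\n'
        f"##contig=<ID={call.ref_name},length={len(ref)}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    info = f"SVTYPE=DEL;END={call.deletion.end};SVLEN=-{call.length};HOMLEN={call.mh_len}"
    return header + f"{call.ref_name}\t{pos1}\t.\t{anchor_base}\t<DEL>\t.\tPASS\t{info}\n"
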