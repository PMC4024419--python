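"""Repeat-annotation tables and the repeat landscape of a locus.

This module reads the whitespace-delimited RepeatMasker ``.out`` dialect
(score, divergence, query coordinates, orientation, repeat name, class/family,
repeat coordinates, linkage id), summarizes per-class base coverage and
element counts, and nominates same-subfamily, same-orientation repeat pairs
as substrates for recombination-mediated deletions (Alu-Alu NAHR).

Coverage is computed on merged intervals so overlapping annotations are never
double-counted, and fragmented elements (several rows sharing a linkage id,
e.g. an L1 interrupted by a younger Alu insertion) count as one element.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence, TextIO

import edlib

from .intervals import GenomicInterval

__all__ = [
    "RepeatFeature",
    "RepeatTable",
    "ClassSummary",
    "RepeatSummary",
    "RepeatPair",
    "RepeatParseError",
    "parse_rm_out",
    "write_rm_out",
    "summarize_repeats",
    "find_recombinogenic_pairs",
    "features_to_bed",
    "alignment_identity",
]

#: class/family names whose coverage is excluded from "interspersed repeats"
NON_INTERSPERSED_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


class RepeatParseError(ValueError):
    """Raised for malformed rows in the ``.out`` dialect; names the line."""


@dataclass(frozen=True)
class RepeatFeature:
    """One annotation row: a (possibly partial) repeat copy in the query."""

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query: GenomicInterval
    orientation: str  # '+' or 'C' (complement, i.e. minus strand)
    repeat_name: str
    class_family: str
    repeat_begin: int
    repeat_end: int
    repeat_left: int
    element_id: int

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "C"):
            raise ValueError(f"orientation must be '+' or 'C', got {self.orientation!r}")
        if self.element_id < 1:
            raise ValueError("element_id must be >= 1")

    @property
    def strand(self) -> str:
        """BED-style strand: RepeatMasker 'C' is the minus strand."""
        return "-" if self.orientation == "C" else "+"

    @property
    def repeat_class(self) -> str:
        """Top-level class, e.g. 'SINE' from 'SINE/Alu'."""
        return self.class_family.split("/", 1)[0]


@dataclass(frozen=True)
class RepeatTable:
    """The ordered repeat annotation of one analyzed query window."""

    region: GenomicInterval
    features: tuple[RepeatFeature, ...]

    def __post_init__(self) -> None:
        for f in self.features:
            if not (
                self.region.start <= f.query.start and f.query.end <= self.region.end
            ):
                raise ValueError(
                    f"feature {f.repeat_name} {f.query.start}-{f.query.end} "
                    f"outside region [{self.region.start}, {self.region.end})"
                )
        object.__setattr__(
            self, "features", tuple(sorted(self.features, key=lambda f: f.query.start))
        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total covered bases of a set of half-open intervals, overlaps merged."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


_HEADER_RE = re.compile(r"^\s*$|^\s*(SW|score|begin|perc)\b", re.IGNORECASE)


def _strip_parens(token: str) -> tuple[int, bool]:
    """Return (value, was_parenthesized) for repeat-coordinate tokens."""
    m = re.fullmatch(r"\((-?\d+)\)?|(-?\d+)\)?", token)
    if m is None:
        raise ValueError(f"bad coordinate token {token!r}")
    paren = m.group(1) is not None
    return int(m.group(1) or m.group(2)), paren


def parse_rm_out(source: str | TextIO, region: GenomicInterval | None = None) -> RepeatTable:
    """Parse the RepeatMasker ``.out`` dialect into a :class:`RepeatTable`.

    Rows are whitespace-delimited: score, %div, %del, %ins, query name,
    query begin/end (1-based inclusive), bases left ``(N)``, orientation
    (``+``/``C``), repeat name, class/family, three repeat-position columns
    (order ``begin end (left)`` on ``+``, ``(left) end begin`` on ``C``),
    and a linkage id. Header lines are tolerated and skipped. The region
    length is inferred from ``query end + bases left`` unless ``region``
    is given explicitly.

    Raises
    ------
    RepeatParseError
        On non-numeric positions, unknown orientation tokens or
        ``end < begin``, naming the offending line number.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    features: list[RepeatFeature] = []
    seq_id = region.seq_id if region is not None else None
    region_len = region.length() if region is not None else 0
    for lineno, line in enumerate(source, start=1):
        tokens = line.split()
        if not tokens or _HEADER_RE.match(line):
            continue
        try:
            int(tokens[0])
        except ValueError:
            # header / continuation line (e.g. the two-line .out banner)
            continue
        if len(tokens) < 15:
            raise RepeatParseError(f"line {lineno}: expected >=15 columns, got {len(tokens)}")
        try:
            sw = int(tokens[0])
            div, dele, ins = (float(t) for t in tokens[1:4])
            qname = tokens[4]
            qbegin, qend = int(tokens[5]), int(tokens[6])
            qleft, _ = _strip_parens(tokens[7])
        except ValueError as exc:
            raise RepeatParseError(f"line {lineno}: {exc}") from None
        orient = tokens[8]
        if orient not in ("+", "C"):
            raise RepeatParseError(f"line {lineno}: unknown orientation token {orient!r}")
        name, class_family = tokens[9], tokens[10]
        try:
            r1, _ = _strip_parens(tokens[11])
            r2, _ = _strip_parens(tokens[12])
            r3, _ = _strip_parens(tokens[13])
            element_id = int(tokens[14])
        except ValueError as exc:
            raise RepeatParseError(f"line {lineno}: {exc}") from None
        if qend < qbegin:
            raise RepeatParseError(f"line {lineno}: query end {qend} < begin {qbegin}")
        if orient == "+":
            rbegin, rend, rleft = r1, r2, r3
        else:  # C rows print (left) end begin
            rleft, rend, rbegin = r1, r2, r3
        if seq_id is None:
            seq_id = qname
        region_len = max(region_len, qend + qleft)
        features.append(
            RepeatFeature(
                sw_score=sw,
                pct_div=div,
                pct_del=dele,
                pct_ins=ins,
                query=GenomicInterval.from_1based(seq_id, qbegin, qend),
                orientation=orient,
                repeat_name=name,
                class_family=class_family,
                repeat_begin=rbegin,
                repeat_end=rend,
                repeat_left=rleft,
                element_id=element_id,
            )
        )
    if region is None:
        if seq_id is None:  # empty stream
            return RepeatTable(GenomicInterval("region", 0, 1), ())
        region = GenomicInterval(seq_id, 0, region_len)
    return RepeatTable(region, tuple(features))


def write_rm_out(table: RepeatTable) -> str:
    """Serialize a :class:`RepeatTable` back to the ``.out`` dialect.

    ``parse_rm_out(write_rm_out(t))`` reproduces the feature list of ``t``.
    """
    lines = [
        "score %div %del %ins query begin end (left) strand repeat class/family "
        "begin end (left) id",
        "",
    ]
    rl = table.region.length()
    for f in table.features:
        b1, e1 = f.query.to_1based()
        if f.orientation == "+":
            rcols = f"{f.repeat_begin} {f.repeat_end} ({f.repeat_left})"
        else:
            rcols = f"({f.repeat_left}) {f.repeat_end} {f.repeat_begin}"
        lines.append(
            f"{f.sw_score} {f.pct_div:.1f} {f.pct_del:.1f} {f.pct_ins:.1f} "
            f"{table.region.seq_id} {b1} {e1} ({rl - e1}) {f.orientation} "
            f"{f.repeat_name} {f.class_family} {rcols} {f.element_id}"
        )
    return "\n".join(lines) + "\n"


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (the reporting convention for fractions)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassSummary:
    covered_bp: int
    element_count: int
    fraction: float  # percent of region length, rounded half-up to 2 dp


@dataclass(frozen=True)
class RepeatSummary:
    """Per-class/family repeat coverage of a region.

    ``interspersed_bp`` is the merged coverage of everything except simple
    repeats and low-complexity runs, mirroring RepeatMasker's own
    "interspersed repeats" line.
    """

    region_length: int
    by_family: dict[str, ClassSummary]
    by_class: dict[str, ClassSummary]
    interspersed_bp: int
    interspersed_fraction: float
    simple_low_bp: int
    total_covered_bp: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "region_length": self.region_length,
                "by_family": {k: vars(v) for k, v in self.by_family.items()},
                "by_class": {k: vars(v) for k, v in self.by_class.items()},
                "interspersed_bp": self.interspersed_bp,
                "interspersed_fraction": self.interspersed_fraction,
                "simple_low_bp": self.simple_low_bp,
                "total_covered_bp": self.total_covered_bp,
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        rows = ["group\tcovered_bp\telement_count\tfraction_pct"]
        for k in sorted(self.by_family):
            v = self.by_family[k]
            rows.append(f"{k}\t{v.covered_bp}\t{v.element_count}\t{v.fraction:.2f}")
        rows.append(
            f"interspersed\t{self.interspersed_bp}\t-\t{self.interspersed_fraction:.2f}"
        )
        return "\n".join(rows) + "\n"


def summarize_repeats(table: RepeatTable) -> RepeatSummary:
    """Summarize per-class coverage, element counts and fractions of a region.

    Covered bases are counted once per grouping (overlaps merged); element
    counts are distinct linkage ids, so a fragmented element counts once.
    """
    if table.region.length() <= 0:
        raise ValueError("region length must be > 0")
    rl = table.region.length()

    def group(keyfunc) -> dict[str, ClassSummary]:
        ivs: dict[str, list[tuple[int, int]]] = {}
        ids: dict[str, set[int]] = {}
        for f in table.features:
            k = keyfunc(f)
            ivs.setdefault(k, []).append((f.query.start, f.query.end))
            ids.setdefault(k, set()).add(f.element_id)
        return {
            k: ClassSummary(
                covered_bp=_merged_length(v),
                element_count=len(ids[k]),
                fraction=_round2(100.0 * _merged_length(v) / rl),
            )
            for k, v in ivs.items()
        }

    by_family = group(lambda f: f.class_family)
    by_class = group(lambda f: f.repeat_class)

    inter_ivs = [
        (f.query.start, f.query.end)
        for f in table.features
        if f.repeat_class not in NON_INTERSPERSED_CLASSES
    ]
    simple_ivs = [
        (f.query.start, f.query.end)
        for f in table.features
        if f.repeat_class in NON_INTERSPERSED_CLASSES
    ]
    interspersed = _merged_length(inter_ivs)
    simple_low = _merged_length(simple_ivs)
    total = _merged_length([(f.query.start, f.query.end) for f in table.features])
    return RepeatSummary(
        region_length=rl,
        by_family=by_family,
        by_class=by_class,
        interspersed_bp=interspersed,
        interspersed_fraction=_round2(100.0 * interspersed / rl),
        simple_low_bp=simple_low,
        total_covered_bp=total,
    )


def alignment_identity(a: str, b: str) -> float:
    """Percent identity from a global (Needleman-Wunsch) alignment.

    Identity = matched columns / total alignment columns * 100, using edlib's
    extended CIGAR. Either sequence empty gives 0.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="path", mode="NW")
    matches = 0
    columns = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns


@dataclass(frozen=True)
class RepeatPair:
    """A candidate deletion substrate: two homologous same-strand repeats."""

    a: RepeatFeature
    b: RepeatFeature
    identity: float
    same_orientation: bool
    inter_repeat_distance: int
    predicted_deletion_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.a.query.start < self.b.query.start:
            raise ValueError("pair must be ordered by query start")


def find_recombinogenic_pairs(
    table: RepeatTable,
    ref: str,
    min_identity: float = 85.0,
    exact_subfamily: bool = True,
) -> list[RepeatPair]:
    """Nominate same-orientation homologous repeat pairs as deletion substrates.

    Pairs must share the exact subfamily name (e.g. AluSq2 vs AluSq2) unless
    ``exact_subfamily=False``, which relaxes matching to the class/family
    column (e.g. any SINE/Alu with any SINE/Alu); must lie on the same strand;
    and must reach ``min_identity`` percent global-alignment identity between
    their query subsequences. The predicted deletion range spans the distances
    between equivalent positions of the two copies: an equal crossover between
    copies A (upstream) and B deletes between ``B.start - A.end`` and
    ``B.end - A.start`` bases.

    Results are ranked by identity descending, ties broken by smaller
    inter-repeat distance, then by coordinate for full determinism.
    """
    if len(ref) != table.region.length():
        raise ValueError(
            f"reference length {len(ref)} != region length {table.region.length()}"
        )
    if not table.features:
        raise ValueError("repeat table is empty")
    off = table.region.start
    pairs: list[RepeatPair] = []
    feats = table.features
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            if a.orientation != b.orientation:
                continue
            if exact_subfamily:
                if a.repeat_name != b.repeat_name:
                    continue
            elif a.class_family != b.class_family:
                continue
            seq_a = ref[a.query.start - off : a.query.end - off]
            seq_b = ref[b.query.start - off : b.query.end - off]
            ident = alignment_identity(seq_a, seq_b)
            if ident < min_identity:
                continue
            pairs.append(
                RepeatPair(
                    a=a,
                    b=b,
                    identity=ident,
                    same_orientation=True,
                    inter_repeat_distance=b.query.start - a.query.end,
                    predicted_deletion_range=(
                        b.query.start - a.query.end,
                        b.query.end - a.query.start,
                    ),
                )
            )
    pairs.sort(
        key=lambda p: (-p.identity, p.inter_repeat_distance, p.a.query.start, p.b.query.start)
    )
    return pairs


def pairs_to_tsv(pairs: Sequence[RepeatPair]) -> str:
    """Pairs as TSV; coordinates 1-based inclusive as in the source files."""
    rows = [
        "a_name\ta_start\ta_end\tb_name\tb_start\tb_end\tstrand\tidentity_pct"
        "\tinter_repeat_distance\tpredicted_del_min\tpredicted_del_max"
    ]
    for p in pairs:
        a1, a2 = p.a.query.to_1based()
        b1, b2 = p.b.query.to_1based()
        rows.append(
            f"{p.a.repeat_name}\t{a1}\t{a2}\t{p.b.repeat_name}\t{b1}\t{b2}\t"
            f"{p.a.strand}\t{p.identity:.2f}\t{p.inter_repeat_distance}\t"
            f"{p.predicted_deletion_range[0]}\t{p.predicted_deletion_range[1]}"
        )
    return "\n".join(rows) + "\n"


def features_to_bed(table: RepeatTable) -> str:
    """BED6 export (0-based half-open; strand from orientation)."""
    lines = []
    for f in table.features:
        lines.append(
            f"{f.query.seq_id}\t{f.query.start}\t{f.query.end}\t"
            f"{f.repeat_name}\t{f.sw_score}\t{f.strand}"
        )
    return "\n".join(lines) + "\n"
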