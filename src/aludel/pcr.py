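"""In-silico PCR: primer binding sites, amplicon prediction, genotype calls.

The deletion screen this supports uses two reactions per sample:

* an *exon* reaction whose primers sit inside the deleted segment — it
  amplifies only from an intact allele;
* a *junction* reaction whose primers flank the deletion — on the wild-type
  allele its product is too long for standard PCR, on the deletion allele the
  product shrinks by the deletion length and becomes detectable.

The pair of presence/absence outcomes is a complete diploid genotype test:
(+,-) wild type, (+,+) heterozygous carrier, (-,+) homozygous deleted,
(-,-) assay failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "Primer",
    "PrimerPair",
    "BindingSite",
    "AmpliconPrediction",
    "DiagnosticCall",
    "revcomp",
    "find_binding_sites",
    "predict_amplicons",
    "call_genotype",
    "run_diagnostic",
    "read_primer_panel",
    "amplicons_to_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3'. The annealing temperature is annotation only."""

    name: str
    seq: str
    annealing_temp: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("primer sequence is empty")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"primer {self.name}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    expected_wt_size: Optional[int] = None
    expected_mut_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.forward.name == self.reverse.name:
            raise ValueError("forward and reverse primers must have distinct names")

    @property
    def name(self) -> str:
        return f"{self.forward.name}/{self.reverse.name}"


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    position: GenomicInterval  # footprint on the template, 0-based half-open
    strand: str  # '+': primer as written; '-': reverse complement on template
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    pair_name: str
    template_id: str
    product: GenomicInterval
    size: int
    detectable: bool

    def __post_init__(self) -> None:
        if self.size != self.product.length():
            raise ValueError("size must equal product interval length")


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)


def find_binding_sites(
    template: str,
    primer: Primer,
    max_mismatch: int = 0,
    exact_3prime: int = 5,
    template_id: str = "template",
) -> list[BindingSite]:
    """All primer binding sites on both strands of a template.

    A site is an ungapped match of the full primer with at most
    ``max_mismatch`` mismatches whose 3'-terminal ``exact_3prime`` bases
    match exactly (extension from a mismatched 3' end fails in practice).
    ``N`` in the primer matches any template base. On the '-' strand the
    reverse complement of the primer is matched against the template; its 3'
    end is then the template-leftmost base of the footprint.

    A primer longer than the template simply has no sites.
    """
    m = len(primer)
    if m > len(template):
        return []
    t = _encode(template)
    sites: list[BindingSite] = []
    windows = np.lib.stride_tricks.sliding_window_view(t, m)

    for strand, pseq in (("+", primer.seq.upper()), ("-", revcomp(primer.seq).upper())):
        p = _encode(pseq)
        informative = p != ord("N")
        mism = (windows != p) & informative
        counts = mism.sum(axis=1)
        if exact_3prime > 0:
            k = min(exact_3prime, m)
            # 3' end of the primer: right end of footprint on '+', left on '-'
            tail = mism[:, -k:] if strand == "+" else mism[:, :k]
            ok3 = ~tail.any(axis=1)
        else:
            ok3 = np.ones(len(windows), dtype=bool)
        hits = np.nonzero((counts <= max_mismatch) & ok3)[0]
        for h in hits:
            sites.append(
                BindingSite(
                    template_id=template_id,
                    position=GenomicInterval(template_id, int(h), int(h) + m),
                    strand=strand,
                    mismatches=int(counts[h]),
                )
            )
    sites.sort(key=lambda s: (s.position.start, s.strand))
    return sites


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    max_product_len: int = 2000,
    max_mismatch: int = 0,
    exact_3prime: int = 5,
    template_id: str = "template",
) -> list[AmpliconPrediction]:
    """Predict PCR products of a primer pair on one template.

    Every combination of a forward-primer '+' site and a reverse-primer '-'
    site with the forward 5' end not downstream of the reverse 3' end yields
    a product, sized from the first base of the forward footprint through the
    last base of the reverse footprint (both primer footprints included).
    ``detectable`` marks products at or under ``max_product_len`` —
    the standard-PCR vs long-range distinction; raise the threshold (e.g.
    12000) to model long-range chemistry. Multiple products are reported,
    never errored.
    """
    fwd_sites = [
        s
        for s in find_binding_sites(template, pair.forward, max_mismatch, exact_3prime, template_id)
        if s.strand == "+"
    ]
    rev_sites = [
        s
        for s in find_binding_sites(template, pair.reverse, max_mismatch, exact_3prime, template_id)
        if s.strand == "-"
    ]
    out: list[AmpliconPrediction] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.position.start > r.position.start:
                continue
            size = r.position.end - f.position.start
            out.append(
                AmpliconPrediction(
                    pair_name=pair.name,
                    template_id=template_id,
                    product=GenomicInterval(template_id, f.position.start, r.position.end),
                    size=size,
                    detectable=size <= max_product_len,
                )
            )
    out.sort(key=lambda a: (a.product.start, a.size))
    return out


@dataclass(frozen=True)
class DiagnosticCall:
    """Outcome of the two-reaction deletion screen for one sample."""

    genotype: str  # WT | HET | HOM_DEL | UNINFORMATIVE
    evidence: dict = field(default_factory=dict)


def call_genotype(exon_detected: bool, junction_detected: bool) -> DiagnosticCall:
    """Genotype from the two reactions' presence/absence outcomes.

    exon+/junction- -> WT; exon+/junction+ -> HET; exon-/junction+ -> HOM_DEL;
    exon-/junction- -> UNINFORMATIVE (assay failure). Total and deterministic.
    """
    table = {
        (True, False): "WT",
        (True, True): "HET",
        (False, True): "HOM_DEL",
        (False, False): "UNINFORMATIVE",
    }
    return DiagnosticCall(
        genotype=table[(bool(exon_detected), bool(junction_detected))],
        evidence={"exon_rxn": bool(exon_detected), "junction_rxn": bool(junction_detected)},
    )


def run_diagnostic(
    alleles: Sequence[str],
    exon_pair: PrimerPair,
    junction_pair: PrimerPair,
    max_product_len: int = 2000,
) -> DiagnosticCall:
    """Run both diagnostic reactions on a sample's allele templates.

    A reaction is positive when any allele yields a detectable product
    (genomic DNA of a diploid sample contains both alleles).
    """

    def detected(pair: PrimerPair) -> bool:
        return any(
            a.detectable
            for tpl in alleles
            for a in predict_amplicons(tpl, pair, max_product_len=max_product_len)
        )

    return call_genotype(detected(exon_pair), detected(junction_pair))


def read_primer_panel(path) -> dict[str, PrimerPair]:
    """Read a primer panel TSV.

    Columns: pair_name, forward_name, forward_seq, reverse_name, reverse_seq,
    annealing_c, expected_wt_bp, expected_mut_bp (the last two may be blank
    or approximate like '~500', carried as annotations).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")

    def _size(v: str) -> Optional[int]:
        v = v.strip().lstrip("~")
        return int(v) if v.isdigit() else None

    panel: dict[str, PrimerPair] = {}
    for _, row in df.iterrows():
        temp = float(row["annealing_c"]) if row["annealing_c"] else None
        panel[row["pair_name"]] = PrimerPair(
            forward=Primer(row["forward_name"], row["forward_seq"], temp),
            reverse=Primer(row["reverse_name"], row["reverse_seq"], temp),
            expected_wt_size=_size(row["expected_wt_bp"]),
            expected_mut_size=_size(row["expected_mut_bp"]),
        )
    return panel


def amplicons_to_tsv(amplicons: Iterable[AmpliconPrediction]) -> str:
    rows = ["pair\ttemplate\tstart_1based\tend_1based\tsize_bp\tdetectable"]
    for a in amplicons:
        s1, e1 = a.product.to_1based()
        rows.append(f"{a.pair_name}\t{a.template_id}\t{s1}\t{e1}\t{a.size}\t{a.detectable}")
    return "\n".join(rows) + "\n"


def genotype_table(calls: dict[str, DiagnosticCall]) -> pd.DataFrame:
    """Per-sample genotype table (sample, exon_rxn, junction_rxn, call)."""
    return pd.DataFrame(
        [
            {
                "sample": s,
                "exon_rxn": c.evidence.get("exon_rxn"),
                "junction_rxn": c.evidence.get("junction_rxn"),
                "call": c.genotype,
            }
            for s, c in sorted(calls.items())
        ]
    )
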