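"""Ground-truth locus simulator.

Generates everything the analysis stages consume, with a known truth bundle:

* a repeat-laden locus (default 9358 bp, ~50% interspersed repeats) built by
  planting diverged copies of packaged *synthetic* Alu-like and L1-like
  consensus sequences on an i.i.d. random background, including two
  same-orientation low-divergence Alu-like copies ~3.9 kb apart;
* an equal-crossover (NAHR) deletion allele joining the upstream copy's 5'
  part to the downstream copy's 3' part inside a shared identical block,
  so the junction carries a multi-bp microhomology;
* an error-free (optionally noisy) Sanger-like junction read;
* consanguineous pedigree genotypes in which affecteds are homozygous for a
  shared founder marker haplotype.

Determinism: all randomness flows from ``SimConfig.seed`` through four
independent spawned streams (background, repeat mutation, junction read,
pedigree), so changing e.g. the pedigree plan never changes the sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .breakpoints import DeletionCall, apply_deletion, deletion_call
from .intervals import GenomicInterval
from .pcr import Primer, PrimerPair, revcomp
from .repeats import RepeatFeature, RepeatTable, features_to_bed, write_rm_out

__all__ = [
    "RepeatPlanEntry",
    "CrossoverPlan",
    "PedigreePlan",
    "JunctionPlan",
    "SimConfig",
    "SimulatedLocus",
    "load_consensus",
    "simulate_locus",
    "simulate_crossover_deletion",
    "simulate_pedigree_genotypes",
    "diagnostic_panel",
    "write_outputs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def load_consensus() -> dict[str, str]:
    """Packaged synthetic repeat consensus sequences (AluSyn ~300 bp, L1Syn ~1 kb)."""
    path = resources.files("aludel.data") / "consensus_synthetic.fasta"
    with path.open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


@dataclass(frozen=True)
class RepeatPlanEntry:
    """One planned repeat insertion (consensus copy pasted over background)."""

    consensus: str  # consensus id, e.g. "AluSyn"
    position: int  # 0-based insertion start in the locus
    orientation: str = "+"  # '+' or 'C'
    divergence: float = 10.0  # percent per-base substitution
    length: Optional[int] = None  # fragment length (None = full consensus)
    consensus_offset: int = 0  # fragment start within the consensus
    element_id: Optional[int] = None  # linkage id; fragments share one
    class_family: str = "SINE/Alu"
    name: Optional[str] = None  # repeat name in the truth table

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 50.0):
            raise ValueError("divergence must be within [0, 50]%")
        if self.orientation not in ("+", "C"):
            raise ValueError("orientation must be '+' or 'C'")


@dataclass(frozen=True)
class CrossoverPlan:
    """Equal-crossover deletion between two planned same-orientation repeats."""

    pair: Optional[tuple[int, int]] = None  # indices into the repeat plan; None = auto
    offset: Optional[int] = None  # crossover offset within the copies; None = auto
    min_block: int = 8  # minimum identical-block length containing the offset
    forced_block: Optional[int] = None  # force the block to exactly this length


@dataclass(frozen=True)
class PedigreePlan:
    """Consanguineous pedigree plan for the founder-haplotype analysis."""

    n_families: int = 10
    affected_per_family: int = 1
    carriers_per_family: int = 2
    markers: tuple[tuple[str, tuple[tuple[int, float], ...]], ...] = (
        ("D6S1582", ((129, 0.35), (131, 0.30), (133, 0.20), (135, 0.15))),
        ("D6S271", ((186, 0.25), (188, 0.35), (190, 0.25), (192, 0.15))),
    )
    founder_haplotype: Optional[tuple[int, ...]] = (129, 188)

    def frequency_tables(self) -> dict[str, dict[int, float]]:
        return {name: dict(freqs) for name, freqs in self.markers}


@dataclass(frozen=True)
class JunctionPlan:
    flank: int = 400  # bases carried on each side of the junction point
    error_rate: float = 0.0  # per-base substitution rate in the read

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error rate must be within [0, 0.1]")


def default_repeat_plan() -> tuple[RepeatPlanEntry, ...]:
    """Default landscape: ~52% interspersed repeats on a 9358 bp locus with
    two '+'-strand low-divergence Alu-like copies at 3081 and 6991 (1-based),
    a fragmented L1 sharing one linkage id, and a simple repeat."""
    E = RepeatPlanEntry
    return (
        E("AluSyn", 650, "C", 12.0, element_id=1, name="AluSyn"),
        E("AluSyn", 1000, "C", 10.0, element_id=2, name="AluSyn"),
        E("L1Syn", 1350, "C", 20.0, length=600, consensus_offset=400,
          element_id=3, class_family="LINE/L1", name="L1Syn"),
        E("AluSyn", 2000, "C", 12.0, element_id=4, name="AluSyn"),
        E("L1Syn", 2350, "C", 15.0, length=700, consensus_offset=0,
          element_id=5, class_family="LINE/L1", name="L1Syn"),
        E("AluSyn", 3080, "+", 2.0, element_id=6, name="AluSyn"),
        E("L1Syn", 3420, "C", 15.0, length=400, consensus_offset=600,
          element_id=5, class_family="LINE/L1", name="L1Syn"),
        E("AluSyn", 3900, "C", 18.0, element_id=7, name="AluSyn"),
        E("L1Syn", 4300, "+", 25.0, length=520, consensus_offset=200,
          element_id=8, class_family="LINE/L2", name="L2Syn"),
        E("AluSyn", 5270, "C", 10.0, element_id=9, name="AluSyn"),
        E("AluSyn", 5600, "+", 0.0, length=36, consensus_offset=0,
          element_id=10, class_family="Simple_repeat", name="(TTTA)n"),
        E("AluSyn", 6990, "+", 2.0, element_id=11, name="AluSyn"),
        E("AluSyn", 7560, "C", 7.0, element_id=12, name="AluSyn"),
        E("AluSyn", 8020, "C", 8.0, element_id=13, name="AluSyn"),
        E("AluSyn", 8600, "+", 20.0, length=110, consensus_offset=100,
          element_id=14, class_family="DNA/hAT-like", name="MER-Syn"),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    locus_length: int = 9358
    ref_name: str = "sim_locus"
    repeats: tuple[RepeatPlanEntry, ...] = field(default_factory=default_repeat_plan)
    crossover: CrossoverPlan = field(default_factory=CrossoverPlan)
    pedigree: PedigreePlan = field(default_factory=PedigreePlan)
    junction: JunctionPlan = field(default_factory=JunctionPlan)


@dataclass(frozen=True)
class SimulatedLocus:
    """Everything the pipeline consumes, plus the truth it should recover."""

    config: SimConfig
    reference: str  # == wild-type allele
    repeat_table: RepeatTable
    deleted_allele: str
    truth_call: DeletionCall
    crossover_offset: int
    junction_read: str
    genotypes: pd.DataFrame
    cohort: tuple[tuple[str, str, str], ...]  # (family, individual, zygosity)

    @property
    def wild_type(self) -> str:
        return self.reference

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "locus_length": self.config.locus_length,
            "ref_name": self.config.ref_name,
            "deletion": {
                "start_1based": self.truth_call.deletion.start + 1,
                "end_1based": self.truth_call.deletion.end,
                "length": self.truth_call.length,
                "mh_len": self.truth_call.mh_len,
                "hgvs_g": self.truth_call.hgvs_g,
            },
            "crossover_offset": self.crossover_offset,
            "n_repeats": len(self.repeat_table.features),
            "n_genotype_rows": int(len(self.genotypes)),
            "founder_haplotype": list(self.config.pedigree.founder_haplotype or ()),
        }


def _mutate(arr: np.ndarray, divergence_pct: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded per-base substitution at the stated divergence (always to a
    different base, so realized divergence equals the rate in expectation)."""
    if divergence_pct <= 0:
        return arr.copy()
    out = arr.copy()
    hit = rng.random(len(arr)) < divergence_pct / 100.0
    idx = np.nonzero(hit)[0]
    if len(idx):
        # shift each hit base by 1-3 positions in the ACGT cycle
        base_idx = np.searchsorted(_BASES, out[idx])
        shift = rng.integers(1, 4, size=len(idx))
        out[idx] = _BASES[(base_idx + shift) % 4]
    return out


def _identical_blocks(ref: np.ndarray, a_start: int, b_start: int, span: int) -> list[tuple[int, int]]:
    """Maximal runs of offsets where copy A and copy B carry identical bases."""
    eq = ref[a_start : a_start + span] == ref[b_start : b_start + span]
    blocks = []
    i = 0
    while i < span:
        if eq[i]:
            j = i
            while j < span and eq[j]:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def simulate_locus(config: SimConfig) -> SimulatedLocus:
    """Build the full ground-truth bundle from a :class:`SimConfig`.

    Deterministic: the same (config, seed) yields byte-identical output.
    Raises on overlapping planned insertions or when no identical block of
    the required length exists between the chosen crossover copies.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_mut, rng_read, rng_ped = (np.random.default_rng(s) for s in ss.spawn(4))

    consensus = load_consensus()
    n = config.locus_length
    ref = _BASES[rng_bg.integers(0, 4, n)].copy()

    # plant repeats (overwriting background keeps coordinates fixed)
    placed: list[tuple[int, int]] = []
    features: list[RepeatFeature] = []
    for k, entry in enumerate(config.repeats):
        cons = consensus[entry.consensus]
        frag = cons[entry.consensus_offset : entry.consensus_offset + (entry.length or len(cons))]
        if entry.class_family == "Simple_repeat":
            unit = "TTTA"
            frag = (unit * (len(frag) // len(unit) + 1))[: len(frag)]
        arr = np.frombuffer(frag.encode(), dtype=np.uint8).copy()
        arr = _mutate(arr, entry.divergence, rng_mut)
        if entry.orientation == "C":
            arr = np.frombuffer(revcomp(arr.tobytes().decode()).encode(), dtype=np.uint8).copy()
        s, e = entry.position, entry.position + len(arr)
        if e > n:
            raise ValueError(f"repeat plan entry {k} extends past the locus end")
        for ps, pe in placed:
            if s < pe and ps < e:
                raise ValueError(f"repeat plan entry {k} overlaps a previous insertion")
        placed.append((s, e))
        ref[s:e] = arr
        rb = entry.consensus_offset + 1
        re_ = entry.consensus_offset + len(arr)
        features.append(
            RepeatFeature(
                sw_score=int(round((100 - entry.divergence) * len(arr) / 10)),
                pct_div=entry.divergence,
                pct_del=0.0,
                pct_ins=0.0,
                query=GenomicInterval(config.ref_name, s, e),
                orientation=entry.orientation,
                repeat_name=entry.name or entry.consensus,
                class_family=entry.class_family,
                repeat_begin=rb,
                repeat_end=re_,
                repeat_left=len(cons) - re_,
                element_id=entry.element_id or (k + 1),
            )
        )
    table = RepeatTable(GenomicInterval(config.ref_name, 0, n), tuple(features))

    # choose the crossover pair
    xp = config.crossover
    if xp.pair is not None:
        ia, ib = xp.pair
    else:
        cands = [
            (i, j)
            for i in range(len(config.repeats))
            for j in range(i + 1, len(config.repeats))
            if config.repeats[i].consensus == config.repeats[j].consensus
            and config.repeats[i].orientation == config.repeats[j].orientation
            and config.repeats[i].class_family == config.repeats[j].class_family
            and config.repeats[i].class_family not in ("Simple_repeat",)
        ]
        if not cands:
            raise ValueError("no eligible same-consensus same-orientation repeat pair")
        # prefer the least diverged pair (the recombination substrate)
        ia, ib = min(
            cands,
            key=lambda p: config.repeats[p[0]].divergence + config.repeats[p[1]].divergence,
        )
    a, b = config.repeats[ia], config.repeats[ib]
    if a.position > b.position:
        a, b = b, a
    span = min(
        (a.length or len(consensus[a.consensus])),
        (b.length or len(consensus[b.consensus])),
    )

    offset = xp.offset
    if xp.forced_block is not None:
        if offset is None:
            offset = max(1, (span - xp.forced_block) // 2)
        ref = _force_block(ref, a.position, b.position, span, offset, xp.forced_block)
        effective_min_block = 0
    else:
        effective_min_block = xp.min_block
        if offset is None:
            blocks = [
                blk
                for blk in _identical_blocks(ref, a.position, b.position, span)
                if blk[1] - blk[0] >= xp.min_block
            ]
            if not blocks:
                raise ValueError(
                    f"no identical block of >= {xp.min_block} bp between the crossover copies"
                )
            blk = max(blocks, key=lambda x: x[1] - x[0])
            offset = (blk[0] + blk[1]) // 2

    ref_str = ref.tobytes().decode()
    deleted, truth = simulate_crossover_deletion(
        ref_str, a.position, b.position, offset, span,
        min_block=effective_min_block, ref_name=config.ref_name,
    )

    # junction read: Sanger-like fragment across the junction point
    jp = a.position + offset  # junction position in the deleted allele
    fl = config.junction.flank
    read = deleted[max(0, jp - fl) : jp + fl]
    if config.junction.error_rate > 0:
        arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        arr = _mutate(arr, config.junction.error_rate * 100.0, rng_read)
        read = arr.tobytes().decode()

    genotypes = simulate_pedigree_genotypes(config.pedigree, rng_ped)
    cohort = _cohort(config.pedigree)
    return SimulatedLocus(
        config=config,
        reference=ref_str,
        repeat_table=table,
        deleted_allele=deleted,
        truth_call=truth,
        crossover_offset=offset,
        junction_read=read,
        genotypes=genotypes,
        cohort=cohort,
    )


def _force_block(
    ref: np.ndarray, a_pos: int, b_pos: int, span: int, offset: int, block_len: int
) -> np.ndarray:
    """Rewrite copy B so the identical block containing the crossover offset
    has exactly ``block_len`` bases (a right-run starting at the offset),
    with mismatches forced at both block boundaries."""
    k, m = offset, block_len
    if not (0 < k and k + m < span):
        raise ValueError("forced block does not fit inside the repeat overlap")
    ref = ref.copy()
    # identical run [k, k+m); mismatches at k-1 and k+m bound it exactly
    ref[b_pos + k : b_pos + k + m] = ref[a_pos + k : a_pos + k + m]

    def _mismatch(at_b: int, vs_a: int) -> None:
        if ref[at_b] == ref[vs_a]:
            i = int(np.searchsorted(_BASES, ref[at_b]))
            ref[at_b] = _BASES[(i + 1) % 4]

    _mismatch(b_pos + k - 1, a_pos + k - 1)
    _mismatch(b_pos + k + m, a_pos + k + m)
    return ref


def simulate_crossover_deletion(
    ref: str,
    a_start: int,
    b_start: int,
    offset: int,
    span: int,
    min_block: int = 0,
    ref_name: str = "sim_locus",
) -> tuple[str, DeletionCall]:
    """Equal-crossover deletion between two aligned repeat copies.

    The deleted allele joins copy A's 5' part (through ``offset - 1``) to
    copy B's part from ``offset`` on; the deletion length is exactly the
    distance between equivalent aligned positions, ``b_start - a_start``.
    The crossover offset must fall inside an identical block of at least
    ``min_block`` bases shared by the two copies.
    """
    if not (0 <= offset < span):
        raise ValueError(f"offset {offset} outside the aligned overlap [0, {span})")
    arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    blocks = _identical_blocks(arr, a_start, b_start, span)
    blk = next((x for x in blocks if x[0] <= offset < x[1]), None)
    if min_block > 0:
        if blk is None or blk[1] - blk[0] < min_block:
            raise ValueError(
                f"crossover offset {offset} not inside an identical block of "
                f">= {min_block} bp"
            )
    start, end = a_start + offset, b_start + offset
    deleted = apply_deletion(ref, GenomicInterval(ref_name, start, end))
    truth = deletion_call(ref, start, end, ref_name=ref_name)
    return deleted, truth


def _draw_allele(freqs: dict[int, float], rng: np.random.Generator,
                 exclude: Optional[int] = None) -> int:
    alleles = [a for a in sorted(freqs) if a != exclude]
    probs = np.array([freqs[a] for a in alleles], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ValueError("allele frequency table has no mass after exclusion")
    return int(rng.choice(alleles, p=probs / total))


def simulate_pedigree_genotypes(plan: PedigreePlan, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format genotype table for consanguineous families.

    With a founder haplotype, affecteds are homozygous for it at every marker
    (identical by descent); carriers are heterozygous founder/non-founder.
    With ``founder_haplotype=None`` (null model) every allele is an
    independent draw from the marker's frequency table.

    Frequencies must sum to 1 per marker.
    """
    freqs = plan.frequency_tables()
    for name, table in freqs.items():
        if abs(sum(table.values()) - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies for {name} do not sum to 1")
        if any(p < 0 for p in table.values()):
            raise ValueError(f"negative allele frequency for {name}")
    founder = plan.founder_haplotype
    if founder is not None and len(founder) != len(plan.markers):
        raise ValueError("founder haplotype length must equal the marker panel size")
    rows = []
    for f in range(plan.n_families):
        fam = f"F{f + 1:02d}"
        members = [(f"{fam}-A{i + 1}", 1, "affected") for i in range(plan.affected_per_family)]
        members += [(f"{fam}-C{i + 1}", 0, "carrier") for i in range(plan.carriers_per_family)]
        for ind, affected, role in members:
            for mi, (marker, _) in enumerate(plan.markers):
                table = freqs[marker]
                if founder is None:
                    a1 = _draw_allele(table, rng)
                    a2 = _draw_allele(table, rng)
                elif role == "affected":
                    a1 = a2 = founder[mi]
                else:  # carrier: one founder allele, one distinct draw
                    a1 = founder[mi]
                    a2 = _draw_allele(table, rng, exclude=founder[mi])
                lo, hi = sorted((a1, a2))
                rows.append(
                    {
                        "family": fam,
                        "individual": ind,
                        "affected": affected,
                        "marker": marker,
                        "allele_a": lo,
                        "allele_b": hi,
                    }
                )
    columns = ["family", "individual", "affected", "marker", "allele_a", "allele_b"]
    return pd.DataFrame(rows, columns=columns)


def _cohort(plan: PedigreePlan) -> tuple[tuple[str, str, str], ...]:
    """POLH-allele zygosity per pedigree member: affecteds are homozygous for
    the deletion, carriers heterozygous (consistent with the marker data)."""
    out = []
    for f in range(plan.n_families):
        fam = f"F{f + 1:02d}"
        for i in range(plan.affected_per_family):
            out.append((fam, f"{fam}-A{i + 1}", "HOM_DEL"))
        for i in range(plan.carriers_per_family):
            out.append((fam, f"{fam}-C{i + 1}", "HET"))
    return tuple(out)


def diagnostic_panel(sim: SimulatedLocus, primer_len: int = 21) -> tuple[PrimerPair, PrimerPair]:
    """Design the two diagnostic primer pairs for a simulated locus.

    The exon-surrogate pair sits fully inside the deleted interval (product
    only from an intact allele); the junction pair flanks the deletion so the
    wild-type product exceeds standard-PCR length while the deletion-allele
    product is short.
    """
    ref = sim.reference
    d = sim.truth_call.deletion
    # exon-surrogate reaction: ~450 bp product centred in the deleted interval
    mid = (d.start + d.end) // 2
    ef_start = mid - 230
    er_end = mid + 229
    if ef_start < d.start + sim.truth_call.mh_len + 10 or er_end > d.end - 10:
        raise ValueError("deleted interval too short for the internal reaction")
    exon_f = Primer("SIM-EX-F", ref[ef_start : ef_start + primer_len])
    exon_r = Primer("SIM-EX-R", revcomp(ref[er_end - primer_len : er_end]))
    # junction reaction: primers ~300 bp outside the ambiguity window
    jf_start = sim.truth_call.ambiguity.start - 300
    jr_end = d.end + 280
    if jf_start < 0 or jr_end > len(ref):
        raise ValueError("locus too short to place junction primers")
    junc_f = Primer("SIM-DEL-F", ref[jf_start : jf_start + primer_len])
    junc_r = Primer("SIM-DEL-R", revcomp(ref[jr_end - primer_len : jr_end]))
    wt_size = jr_end - jf_start
    return (
        PrimerPair(exon_f, exon_r, expected_wt_size=er_end - ef_start),
        PrimerPair(junc_f, junc_r, expected_wt_size=wt_size,
                   expected_mut_size=wt_size - sim.truth_call.length),
    )


def write_outputs(sim: SimulatedLocus, outdir: str | Path) -> Path:
    """Write all simulator artifacts under one directory with a manifest index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _fasta(path: Path, name: str, seq: str, desc: str = "") -> None:
        SeqIO.write([SeqRecord(Seq(seq), id=name, description=desc)], path, "fasta")

    name = sim.config.ref_name
    _fasta(outdir / "reference.fasta", name, sim.reference, "simulated wild-type locus")
    _fasta(outdir / "deleted_allele.fasta", f"{name}_del", sim.deleted_allele,
           "simulated deletion allele")
    _fasta(outdir / "junction_read.fasta", f"{name}_junction", sim.junction_read,
           "simulated junction amplicon read")
    (outdir / "repeats.out").write_text(write_rm_out(sim.repeat_table))
    (outdir / "repeats.bed").write_text(features_to_bed(sim.repeat_table))
    sim.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    pd.DataFrame(sim.cohort, columns=["family", "individual", "zygosity"]).to_csv(
        outdir / "cohort.tsv", sep="\t", index=False
    )
    manifest = sim.manifest()
    manifest["files"] = sorted(
        p.name for p in outdir.iterdir() if p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir / "manifest.json"
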