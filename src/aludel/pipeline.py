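"""Pipeline orchestration: stages, configuration, and the run report.

Each stage is a plain function that reads its inputs (files or the simulator
bundle), runs one analysis module, and writes its artifacts atomically under
the output directory. ``run("all", cfg)`` chains simulation -> repeat
summary -> pair nomination -> junction mapping -> virtual PCR -> cohort
genotyping -> founder report -> a single JSON+Markdown report whose numbers
are read back from the stage files (never recomputed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import breakpoints, founder, pcr, repeats, simulate
from .intervals import GenomicInterval

__all__ = ["PipelineConfig", "PipelineError", "run", "SUBCOMMANDS"]

log = logging.getLogger("aludel")

SUBCOMMANDS = (
    "simulate",
    "annotate",
    "pairs",
    "map-junction",
    "pcr",
    "genotype",
    "founder",
    "report",
    "all",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the problem."""


@dataclass
class PipelineConfig:
    """Run configuration; flags > config file > defaults precedence is
    applied by the CLI before this object is built."""

    outdir: Path = Path("aludel_out")
    seed: int = 0
    simulate: bool = True
    # explicit inputs (used when simulate is off)
    reference_fasta: Optional[Path] = None
    repeats_out: Optional[Path] = None
    junction_fasta: Optional[Path] = None
    primer_tsv: Optional[Path] = None
    genotypes_tsv: Optional[Path] = None
    panel_tsv: Optional[Path] = None
    # thresholds
    min_identity: float = 85.0
    exact_subfamily: bool = True
    max_mismatch: int = 0
    max_product_len: int = 2000
    anchor_k: int = 25
    relax: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        self.outdir = Path(self.outdir)
        if not (50.0 <= self.min_identity <= 100.0):
            raise PipelineError("config: min_identity must be within [50, 100]")
        if self.max_product_len < 50:
            raise PipelineError("config: max_product_len must be >= 50")
        if self.anchor_k < 8:
            raise PipelineError("config: anchor_k must be >= 8")
        if not self.simulate:
            for name in ("reference_fasta", "repeats_out"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"config: {name} required (and must exist) "
                                        "when simulate is off")


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_fasta_first(path: Path) -> tuple[str, str]:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq)


def _load_sim(cfg: PipelineConfig) -> simulate.SimulatedLocus:
    return simulate.simulate_locus(simulate.SimConfig(seed=cfg.seed))


def stage_simulate(cfg: PipelineConfig) -> Path:
    sim = _load_sim(cfg)
    return simulate.write_outputs(sim, cfg.outdir / "sim")


def _inputs(cfg: PipelineConfig):
    """Resolve (ref_name, ref_seq, repeat table, junction seq) from the
    simulate block or explicit paths."""
    if cfg.simulate:
        simdir = cfg.outdir / "sim"
        if not (simdir / "manifest.json").exists():
            stage_simulate(cfg)
        name, ref = _read_fasta_first(simdir / "reference.fasta")
        table = repeats.parse_rm_out((simdir / "repeats.out").read_text())
        _, junction = _read_fasta_first(simdir / "junction_read.fasta")
        return name, ref, table, junction
    name, ref = _read_fasta_first(Path(cfg.reference_fasta))
    table = repeats.parse_rm_out(Path(cfg.repeats_out).read_text())
    junction = None
    if cfg.junction_fasta:
        _, junction = _read_fasta_first(Path(cfg.junction_fasta))
    return name, ref, table, junction


def stage_annotate(cfg: PipelineConfig) -> Path:
    if cfg.simulate:
        _, _, table, _ = _inputs(cfg)
    else:
        table = repeats.parse_rm_out(Path(cfg.repeats_out).read_text())
    summary = repeats.summarize_repeats(table)
    _atomic_write(cfg.outdir / "repeat_summary.json", summary.to_json())
    _atomic_write(cfg.outdir / "repeat_summary.tsv", summary.to_tsv())
    _atomic_write(cfg.outdir / "repeats.bed", repeats.features_to_bed(table))
    return cfg.outdir / "repeat_summary.json"


def stage_pairs(cfg: PipelineConfig) -> Path:
    name, ref, table, _ = _inputs(cfg)
    pairs = repeats.find_recombinogenic_pairs(
        table, ref, min_identity=cfg.min_identity, exact_subfamily=cfg.exact_subfamily
    )
    _atomic_write(cfg.outdir / "repeat_pairs.tsv", repeats.pairs_to_tsv(pairs))
    return cfg.outdir / "repeat_pairs.tsv"


def stage_map_junction(cfg: PipelineConfig) -> Path:
    name, ref, _, junction = _inputs(cfg)
    if junction is None:
        raise PipelineError("map-junction: no junction sequence (set junction_fasta)")
    call = breakpoints.map_deletion_junction(
        ref, junction, anchor_k=cfg.anchor_k, ref_name=name
    )
    _atomic_write(cfg.outdir / "deletion.json", call.to_json())
    _atomic_write(cfg.outdir / "deletion.vcf", breakpoints.call_to_vcf(call, ref))
    return cfg.outdir / "deletion.json"


def stage_pcr(cfg: PipelineConfig) -> Path:
    name, ref, _, _ = _inputs(cfg)
    preds = []
    if cfg.simulate:
        sim = _load_sim(cfg)
        exon_pair, junction_pair = simulate.diagnostic_panel(sim)
        templates = {"wild_type": sim.reference, "deleted_allele": sim.deleted_allele}
        pairs = {"exon": exon_pair, "junction": junction_pair}
    else:
        if not cfg.primer_tsv:
            raise PipelineError("pcr: no primer panel (set primer_tsv)")
        pairs = pcr.read_primer_panel(cfg.primer_tsv)
        templates = {name: ref}
    for tpl_name, tpl in templates.items():
        for pair_key, pair in pairs.items():
            preds.extend(
                pcr.predict_amplicons(
                    tpl, pair, max_product_len=cfg.max_product_len,
                    max_mismatch=cfg.max_mismatch, template_id=tpl_name,
                )
            )
    _atomic_write(cfg.outdir / "amplicons.tsv", pcr.amplicons_to_tsv(preds))
    return cfg.outdir / "amplicons.tsv"


def stage_genotype(cfg: PipelineConfig) -> Path:
    if not cfg.simulate:
        raise PipelineError("genotype: cohort genotyping needs the simulate block "
                            "(real-sample templates are not modelled)")
    sim = _load_sim(cfg)
    exon_pair, junction_pair = simulate.diagnostic_panel(sim)
    allele_sets = {
        "WT": [sim.reference, sim.reference],
        "HET": [sim.reference, sim.deleted_allele],
        "HOM_DEL": [sim.deleted_allele, sim.deleted_allele],
    }
    calls = {}
    truth = {}
    for fam, ind, zyg in sim.cohort:
        calls[ind] = pcr.run_diagnostic(
            allele_sets[zyg], exon_pair, junction_pair,
            max_product_len=cfg.max_product_len,
        )
        truth[ind] = zyg
    # two unrelated controls
    for ind in ("CTRL-1", "CTRL-2"):
        calls[ind] = pcr.run_diagnostic(
            allele_sets["WT"], exon_pair, junction_pair,
            max_product_len=cfg.max_product_len,
        )
        truth[ind] = "WT"
    df = pcr.genotype_table(calls)
    df["truth"] = df["sample"].map(truth)
    _atomic_write(cfg.outdir / "genotype_calls.tsv", df.to_csv(sep="\t", index=False))
    _atomic_write(
        cfg.outdir / "genotype_calls.json",
        json.dumps(
            {s: {"call": c.genotype, **c.evidence} for s, c in sorted(calls.items())},
            indent=2, sort_keys=True,
        ),
    )
    return cfg.outdir / "genotype_calls.tsv"


def stage_founder(cfg: PipelineConfig) -> Path:
    if cfg.simulate:
        sim = _load_sim(cfg)
        df = sim.genotypes
        panel = [
            founder.MarkerDef(name, i + 1)
            for i, (name, _) in enumerate(sim.config.pedigree.markers)
        ]
    else:
        if not (cfg.genotypes_tsv and cfg.panel_tsv):
            raise PipelineError("founder: need genotypes_tsv and panel_tsv")
        df = founder.read_genotypes_tsv(cfg.genotypes_tsv)
        panel = founder.read_panel_tsv(cfg.panel_tsv)
    profiles = founder.profiles_from_table(df, panel)
    report = founder.shared_homozygous_haplotype(profiles, panel, relax=cfg.relax)
    _atomic_write(cfg.outdir / "founder.json", report.to_json())
    _atomic_write(
        cfg.outdir / "haplotype_matrix.tsv",
        founder.haplotype_matrix(report).to_csv(sep="\t", index=False),
    )
    return cfg.outdir / "founder.json"


_REPORT_INPUTS = {
    "repeat_summary": "repeat_summary.json",
    "repeat_pairs": "repeat_pairs.tsv",
    "deletion": "deletion.json",
    "amplicons": "amplicons.tsv",
    "genotype_calls": "genotype_calls.tsv",
    "founder": "founder.json",
}


def stage_report(cfg: PipelineConfig) -> Path:
    missing = [
        f for f in _REPORT_INPUTS.values() if not (cfg.outdir / f).exists()
    ]
    if missing:
        raise PipelineError(f"report: missing stage artifacts: {', '.join(sorted(missing))}")
    from . import __version__

    report: dict = {
        "provenance": {"seed": cfg.seed, "tool": "aludel", "version": __version__}
    }
    report["repeat_summary"] = json.loads((cfg.outdir / "repeat_summary.json").read_text())
    report["deletion"] = json.loads((cfg.outdir / "deletion.json").read_text())
    report["founder"] = json.loads((cfg.outdir / "founder.json").read_text())
    gcalls = pd.read_csv(cfg.outdir / "genotype_calls.tsv", sep="\t")
    report["genotype_calls"] = gcalls.to_dict(orient="records")
    pairs_lines = (cfg.outdir / "repeat_pairs.tsv").read_text().strip().splitlines()
    report["n_repeat_pairs"] = max(0, len(pairs_lines) - 1)
    _atomic_write(cfg.outdir / "report.json", json.dumps(report, indent=2, sort_keys=True))

    md = [
        "# aludel run report",
        "",
        f"- interspersed repeats: {report['repeat_summary']['interspersed_bp']} bp "
        f"({report['repeat_summary']['interspersed_fraction']}% of "
        f"{report['repeat_summary']['region_length']} bp)",
        f"- candidate recombinogenic pairs: {report['n_repeat_pairs']}",
        f"- mapped deletion: {report['deletion']['hgvs_g']} "
        f"(microhomology {report['deletion']['mh_len']} bp)",
        f"- founder haplotype candidates: "
        f"{['-'.join(map(str, c)) for c in report['founder']['candidates']]} "
        f"({report['founder']['families_supporting']}/"
        f"{report['founder']['families_total']} families)",
        f"- genotype calls: {len(report['genotype_calls'])} samples",
        "",
    ]
    _atomic_write(cfg.outdir / "report.md", "\n".join(md))
    return cfg.outdir / "report.json"


_STAGES = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "pairs": stage_pairs,
    "map-junction": stage_map_junction,
    "pcr": stage_pcr,
    "genotype": stage_genotype,
    "founder": stage_founder,
    "report": stage_report,
}


def run(subcommand: str, cfg: PipelineConfig) -> Path:
    """Run one stage (or ``all``); returns the primary artifact path.

    Raises :class:`PipelineError` naming the failing stage.
    """
    if subcommand not in SUBCOMMANDS:
        raise PipelineError(f"unknown subcommand {subcommand!r}; "
                            f"choose from {', '.join(SUBCOMMANDS)}")
    order = list(_STAGES) if subcommand == "all" else [subcommand]
    if subcommand == "all" and not cfg.simulate:
        order.remove("simulate")
        order.remove("genotype")  # needs simulated cohorts
    last = None
    for name in order:
        log.info("stage %s starting", name)
        try:
            last = _STAGES[name](cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{name}: {exc}") from exc
        log.info("stage %s done -> %s", name, last)
    return last
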