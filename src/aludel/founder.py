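"""Homozygosity and founder-haplotype analysis over microsatellite genotypes.

In consanguineous families a recessive disease allele is expected to be
identical by descent, so affected individuals are homozygous across markers
flanking the locus, and unrelated families descending from one founder share
the same homozygous marker haplotype. Under that assumption no phasing is
needed: an affected individual's homozygous genotypes *are* their haplotype.

Alleles are coded as integer fragment sizes in bp (e.g. the 129-188
haplotype of a dinucleotide-repeat panel); no stutter/binning model.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MarkerDef",
    "MarkerGenotype",
    "FounderReport",
    "homozygosity_profile",
    "homozygous_vector",
    "shared_homozygous_haplotype",
    "read_genotypes_tsv",
    "read_panel_tsv",
    "haplotype_matrix",
]


@dataclass(frozen=True)
class MarkerDef:
    """A microsatellite marker and its ordered map position around the locus."""

    name: str
    map_position: int  # rank along the chromosome; the locus sits between ranks
    side: Optional[str] = None  # 'cen' or 'tel' of the locus, if known


@dataclass(frozen=True)
class MarkerGenotype:
    """One individual's allele pair (fragment sizes, bp) at one marker."""

    individual: str
    marker: str
    allele_a: int = 0
    allele_b: int = 0
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing and (self.allele_a <= 0 or self.allele_b <= 0):
            raise ValueError(
                f"{self.individual}@{self.marker}: alleles must be > 0 unless missing"
            )


HOM, HET, MISSING = "hom", "het", "missing"


def homozygosity_profile(
    genotypes: Iterable[MarkerGenotype], panel: Sequence[MarkerDef]
) -> dict[str, tuple]:
    """Per-marker state for one individual.

    Returns ``{marker: ('hom', allele) | ('het',) | ('missing',)}`` over the
    panel; markers without a genotype are 'missing'. An individual may carry
    at most one genotype per marker.
    """
    seen: dict[str, MarkerGenotype] = {}
    for g in genotypes:
        if g.marker in seen:
            raise ValueError(f"duplicate genotype for {g.individual}@{g.marker}")
        seen[g.marker] = g
    profile: dict[str, tuple] = {}
    for m in panel:
        g = seen.get(m.name)
        if g is None or g.missing:
            profile[m.name] = (MISSING,)
        elif g.allele_a == g.allele_b:
            profile[m.name] = (HOM, g.allele_a)
        else:
            profile[m.name] = (HET,)
    return profile


def homozygous_vector(
    profile: Mapping[str, tuple], panel: Sequence[MarkerDef]
) -> Optional[tuple[int, ...]]:
    """The full homozygous allele vector, or None if any marker is het/missing."""
    vec = []
    for m in panel:
        state = profile.get(m.name, (MISSING,))
        if state[0] != HOM:
            return None
        vec.append(state[1])
    return tuple(vec)


@dataclass(frozen=True)
class FounderReport:
    """Result of the haplotype-sharing analysis across families.

    ``candidates`` are homozygous allele vectors shared by affecteds of at
    least two distinct families, ordered by support (then lexically);
    ``families_supporting`` counts, for the leading candidate, families all
    of whose typed affecteds match it.
    """

    panel: tuple[str, ...]
    profiles: dict  # family -> individual -> profile
    candidates: tuple[tuple[int, ...], ...]
    support: dict  # candidate vector -> families supporting
    families_supporting: int
    families_total: int

    def __post_init__(self) -> None:
        if self.families_supporting > self.families_total:
            raise ValueError("families_supporting cannot exceed families_total")

    @property
    def founder_haplotype(self) -> Optional[tuple[int, ...]]:
        return self.candidates[0] if self.candidates else None

    def to_json(self) -> str:
        return json.dumps(
            {
                "panel": list(self.panel),
                "candidates": [list(c) for c in self.candidates],
                "support": {"-".join(map(str, k)): v for k, v in self.support.items()},
                "families_supporting": self.families_supporting,
                "families_total": self.families_total,
                "profiles": {
                    fam: {ind: {m: list(s) for m, s in prof.items()} for ind, prof in d.items()}
                    for fam, d in self.profiles.items()
                },
            },
            indent=2,
            sort_keys=True,
        )


def _matches(
    profile: Mapping[str, tuple],
    candidate: tuple[int, ...],
    panel: Sequence[MarkerDef],
    allowed_discordant: int,
) -> bool:
    """Does an affected's profile match the candidate at every typed marker?

    Missing markers are ignored; het or differently homozygous typed markers
    are discordant. ``allowed_discordant`` of 1 encodes a one-step variant
    haplotype (e.g. 129-186 against a 129-188 founder).
    """
    discordant = 0
    for m, want in zip(panel, candidate):
        state = profile.get(m.name, (MISSING,))
        if state[0] == MISSING:
            continue
        if state[0] != HOM or state[1] != want:
            discordant += 1
    return discordant <= allowed_discordant


def shared_homozygous_haplotype(
    profiles_by_family: Mapping[str, Mapping[str, Mapping[str, tuple]]],
    panel: Sequence[MarkerDef],
    relax: bool = False,
) -> FounderReport:
    """Find founder-haplotype candidates shared across families.

    ``profiles_by_family`` maps family -> affected individual -> profile
    (from :func:`homozygosity_profile`; include affecteds only). A candidate
    is any full homozygous allele vector carried by affecteds of >= 2
    distinct families. A family supports a candidate when all of its typed
    affecteds match it (``relax=True`` tolerates one discordant marker per
    individual). Output is independent of input order.
    """
    if not profiles_by_family:
        raise ValueError("no families provided")
    panel = sorted(panel, key=lambda m: (m.map_position, m.name))
    fam_vectors: dict[tuple[int, ...], set[str]] = {}
    for fam in profiles_by_family:
        for ind, prof in profiles_by_family[fam].items():
            vec = homozygous_vector(prof, panel)
            if vec is not None:
                fam_vectors.setdefault(vec, set()).add(fam)
    candidates = [v for v, fams in fam_vectors.items() if len(fams) >= 2]

    allowed = 1 if relax else 0
    support: dict[tuple[int, ...], int] = {}
    for cand in candidates:
        n = sum(
            1
            for fam, members in profiles_by_family.items()
            if members
            and all(_matches(prof, cand, panel, allowed) for prof in members.values())
        )
        support[cand] = n
    candidates.sort(key=lambda c: (-support[c], c))
    return FounderReport(
        panel=tuple(m.name for m in panel),
        profiles={f: dict(d) for f, d in profiles_by_family.items()},
        candidates=tuple(candidates),
        support=support,
        families_supporting=support[candidates[0]] if candidates else 0,
        families_total=len(profiles_by_family),
    )


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Long-format genotype table: family, individual, affected, marker,
    allele_a, allele_b. ``affected`` is 1/0; 0 alleles mean missing."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"family", "individual", "affected", "marker", "allele_a", "allele_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotype TSV missing columns: {sorted(missing)}")
    return df


def read_panel_tsv(path) -> list[MarkerDef]:
    """Marker panel TSV: marker, map_position[, side]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    side = "side" in df.columns
    return [
        MarkerDef(r["marker"], int(r["map_position"]), r["side"] if side else None)
        for _, r in df.iterrows()
    ]


def profiles_from_table(
    df: pd.DataFrame, panel: Sequence[MarkerDef], affected_only: bool = True
) -> dict[str, dict[str, dict[str, tuple]]]:
    """Group a long-format genotype table into per-family affected profiles."""
    out: dict[str, dict[str, dict[str, tuple]]] = {}
    if affected_only:
        df = df[df["affected"].astype(int) == 1]
    for (fam, ind), sub in df.groupby(["family", "individual"], sort=True):
        genos = [
            MarkerGenotype(
                individual=str(ind),
                marker=str(r["marker"]),
                allele_a=int(r["allele_a"]),
                allele_b=int(r["allele_b"]),
                missing=int(r["allele_a"]) <= 0 or int(r["allele_b"]) <= 0,
            )
            for _, r in sub.iterrows()
        ]
        out.setdefault(str(fam), {})[str(ind)] = homozygosity_profile(genos, panel)
    return out


def haplotype_matrix(report: FounderReport) -> pd.DataFrame:
    """Per-individual marker states as a family x marker matrix (TSV-ready)."""
    rows = []
    for fam in sorted(report.profiles):
        for ind in sorted(report.profiles[fam]):
            prof = report.profiles[fam][ind]
            row = {"family": fam, "individual": ind}
            for m in report.panel:
                state = prof.get(m, (MISSING,))
                row[m] = state[1] if state[0] == HOM else state[0]
            rows.append(row)
    return pd.DataFrame(rows)
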