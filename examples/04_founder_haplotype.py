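"""Founder-haplotype analysis over simulated consanguineous pedigrees.

Affected members of inbred families are expected to be homozygous (identical
by descent) at microsatellite markers flanking a recessive disease locus; a
haplotype shared homozygously across unrelated families supports a common
founder. Here ten simulated families all carry a planted (129, 188) founder
haplotype.
"""

import numpy as np

from aludel import MarkerDef, shared_homozygous_haplotype
from aludel.founder import profiles_from_table
from aludel.simulate import PedigreePlan, simulate_pedigree_genotypes

plan = PedigreePlan(n_families=10, founder_haplotype=(129, 188))
rng = np.random.default_rng(1)
genotypes = simulate_pedigree_genotypes(plan, rng)
panel = [MarkerDef(name, i + 1) for i, (name, _) in enumerate(plan.markers)]

profiles = profiles_from_table(genotypes, panel)
report = shared_homozygous_haplotype(profiles, panel)

print(f"marker panel: {', '.join(report.panel)}")
print(f"candidate founder haplotypes: "
      f"{['-'.join(map(str, c)) for c in report.candidates]}")
print(f"families supporting the leading candidate: "
      f"{report.families_supporting}/{report.families_total}")
# Every affected is homozygous 129 at the first marker and 188 at the
# second, so the shared 129-188 haplotype is recovered in all families.
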