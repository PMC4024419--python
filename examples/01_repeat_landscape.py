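"""Repeat landscape of a locus window from a RepeatMasker-style table.

Loads the packaged annotation of the 9358 bp exon 9-11 window of POLH,
summarizes per-class coverage, and nominates same-subfamily, same-orientation
repeat pairs as candidate substrates for recombination-mediated deletion.
The pair ranking here uses the default simulated locus for sequence identity
(the packaged table ships without its genomic sequence).
"""

from importlib import resources

from aludel import find_recombinogenic_pairs, parse_rm_out, summarize_repeats
from aludel.simulate import SimConfig, simulate_locus

table = parse_rm_out(
    (resources.files("aludel.data") / "polh_exon9_11_repeats.out").read_text()
)
summary = summarize_repeats(table)

print(f"region length: {summary.region_length} bp")
print(
    f"interspersed repeats: {summary.interspersed_bp} bp "
    f"({summary.interspersed_fraction}%)"
)
for fam in ("SINE/Alu",):
    cs = summary.by_family[fam]
    print(f"{fam}: {cs.covered_bp} bp in {cs.element_count} elements ({cs.fraction}%)")
line = summary.by_class["LINE"]
print(f"LINE: {line.covered_bp} bp in {line.element_count} elements ({line.fraction}%)")

# candidate substrate pairs need sequence; use the simulator's locus, whose
# repeat layout mirrors the annotated window
sim = simulate_locus(SimConfig(seed=0))
pairs = find_recombinogenic_pairs(sim.repeat_table, sim.reference, min_identity=85.0)
top = pairs[0]
print(
    f"top candidate pair: {top.a.repeat_name} @{top.a.query.to_1based()} + "
    f"{top.b.repeat_name} @{top.b.query.to_1based()}, identity {top.identity:.1f}%, "
    f"predicted deletion {top.predicted_deletion_range[0]}-{top.predicted_deletion_range[1]} bp"
)
# An equal crossover between the two top-ranked Alu copies would delete the
# sequence between equivalent positions -- the range printed above.
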