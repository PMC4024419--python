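# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open; every 1-based inclusive
format (RepeatMasker `.out` query columns, HGVS, TSV exports, VCF `POS`/`END`)
converts at the I/O boundary only. RepeatMasker orientation `C` is treated as
the minus strand, and `C` rows carry their repeat-internal coordinates in
`(left) end begin` order, as in the `.out` dialect. The region length of a
parsed table is inferred as `query end + bases-left`, which is consistent
across every row of the packaged table (9358 bp).

The packaged annotation of the *POLH* exon 9–11 window carries a caveat its
own source leaves open: the narrative describes an analyzed span of roughly
3.1 kb (chr6:43578281–43581387) while the table itself covers the 9358 bp
window 43572521–43581878. The package follows the table, since all of its
row coordinates and the published coverage sums are consistent with the
9358 bp window only.

## Repeat landscape

Covered bp per class/family are computed on merged intervals so overlapping
annotations are never double-counted (the packaged table has no overlaps, so
its sums are reproduced either way). Element counts are distinct linkage
ids: the three L1MB8 fragments interrupted by younger insertions share id 5
and count as one LINE element, giving the published 3 LINE elements over
1789 bp and 11 Alu elements over 2908 bp; everything except
`Simple_repeat`/`Low_complexity` contributes to the interspersed fraction
(4814 bp = 51.44% of 9358). Reported fractions are rounded half-up to two
decimals, matching the printed values (31.08%, 19.12%, 51.44%).

Pair nomination ("recombinogenic pairs") requires identical orientation and,
by default, an exact subfamily-name match (AluSq2 ≠ AluSq); a flag relaxes
this to the class/family column. Identity is matches over alignment columns
of a Needleman–Wunsch global alignment (edlib extended CIGAR) of the two
query subsequences — the conventional metric, since no specific one is
mandated by the underlying analysis. Ranking is identity-descending with
ties broken by smaller inter-repeat distance, then coordinates, so output is
fully deterministic and symmetric in input order.

## Junction mapping and microhomology

The mapper implements, as exact string arithmetic, the manual procedure of
calling breakpoints at the last nucleotide of identity between wild-type and
mutant traces: unique exact k-mer anchors at the two junction ends (default
k = 25 — long enough that a random 25-mer is effectively unique at locus
scale, short enough to sit comfortably inside a Sanger-quality flank),
base-by-base extension, deletion length `d = (ref span) − (junction
length)`. Extension is case-insensitive and stops at non-ACGT characters.

Microhomology is defined operationally as the slide freedom of the deletion:
`placement_window` extends left while `ref[lo−1] == ref[lo−1+d]` and right
while `ref[hi] == ref[hi+d]`; the microhomology length `m = hi − lo` yields
exactly `m + 1` equivalent placements, each producing the same mutant
sequence (property-tested against an O(n·m) brute-force string-equality
oracle, and exhaustively on small references). The canonical reported
placement is the 3′-most (the HGVS normalization rule); the full ambiguity
window is carried alongside so no information is lost relative to the
overlap-block presentation customary in breakpoint figures.

An optional error-tolerant mode allows a configurable number of mismatches
per extension (default 0). It is intentionally off by default: a sequencing
error inside the homology block shortens the reported overlap in exact mode
and can lengthen it in tolerant mode, i.e. the mode changes microhomology
semantics. Clean Sanger consensus input is the assumed default.

HGVS handling validates length suffixes against coordinate spans and reports
inconsistencies rather than correcting them. This matters for the locus that
motivated the package: two published genomic coordinate pairs for the same
event (g.36847_40771del3925 and g.32438_36363del3926) are each internally
consistent but mutually incompatible (3925 vs 3926 bp, offset ~4.4 kb), and
two reference records are named for the same deletion. The package validates
both descriptions and deliberately does not decide which is authoritative.
The cDNA description (c.1370-2567_1539+1188del3925) is handled by resolving
both endpoints through an exon map and applying the signed intronic offsets;
for a single deleted exon of length 170 with offsets 2567 and 1188 this
gives 3925 bp, agreeing with the first genomic description.

## In-silico PCR

Binding sites are ungapped full-length matches on either strand within a
mismatch budget (default 0) whose 3′-terminal bases (default 5) match
exactly — the pragmatic model of primer extension failure from a mismatched
3′ end. `N` in a primer matches anything. The implementation is a vectorized
sliding-window comparison; tests check it against an independent per-offset
scan.

Product size runs from the first base of the forward footprint through the
last base of the reverse footprint (both primers included). This convention
reproduces the diagnostic arithmetic the screen relies on: a 4526 bp
wild-type junction amplicon minus a 3925 bp deletion leaves ~600 bp,
detectable by standard PCR; and for any deletion strictly inside an
amplicon, mutant size = wild-type size − deletion length, exactly.

Detectability is a single threshold on product length (default 2000 bp,
configurable; ~12000 models long-range chemistry). It models the
standard-vs-long-range distinction only; thermodynamics (Tm, dimers,
polymerase processivity) are out of scope and annealing temperatures are
carried as annotations. The genotype caller is a total function of the two
reactions' presence/absence outcomes; multiple or nonspecific products are
reported, never errored, and only detectability feeds the call.

## Founder analysis

Under consanguinity the affected's homozygous genotypes are taken as the
haplotype — no phasing algorithm is implemented, which is precisely the
inference the study design licenses. Alleles are integer fragment sizes
(bp). A founder candidate is a full homozygous allele vector shared by
affecteds of at least two distinct families; family support requires all
typed affecteds to match, with a relax flag tolerating one discordant marker
per individual (encoding reported one-step variant haplotypes such as
129–186 beside 129–188). Missing markers are ignored for matching; with the
relax flag off, a supporting affected matches every typed marker exactly.
Output is independent of family/individual input order.

Two marker panels ship as fixtures because the underlying study names the
flanking markers inconsistently between its design (D6S207, D6S1582) and its
results (D6S1582, D6S271); the panel is user-defined and the discrepancy is
documented, not resolved.

Under the null model (independent allele draws, no founder), the probability
that all F families spuriously share some fully homozygous haplotype is
`∏_m Σ_a p_{m,a}^(2F)`; the simulator's null mode is checked against this
closed form by Monte Carlo (≥ 1000 replicates, 3 SE tolerance).

## Simulator

The simulator is first-class, tested code. Design choices:

- **Consensus stand-ins.** Repeat copies derive from packaged *synthetic*
  consensus strings (~300 bp Alu-like, ~1 kb L1-fragment-like), generated
  once from a fixed RNG and frozen (`data/consensus_synthetic.fasta`). They
  are not Repbase extracts; the identity structure between planted copies is
  what the analyses exercise, not the biological motif content.
- **Default landscape.** 9358 bp locus, i.i.d. uniform background, and a
  repeat plan mirroring the annotated window's gross structure: nine
  Alu-like copies, a fragmented L1 sharing one linkage id, an L2-like and a
  DNA-transposon-like fragment, one simple repeat — ~53% interspersed — with
  the two crossover substrates at 1-based starts 3081 and 6991 ('+', 2%
  divergence each), 3910 bp apart, like the real substrate pair. Insertions
  overwrite background at fixed positions (coordinates stay put; overlap is
  an error).
- **Divergence model.** Seeded per-base substitution at the stated rate
  (always to a different base); no indels, so copies stay co-linear and
  identical blocks are computable by direct position-wise comparison.
- **Crossover.** Clean equal recombination at an offset inside an identical
  block shared by the two copies: deleted allele = A's 5′ part + B's 3′
  part; deletion length = distance between copy starts; true microhomology =
  the identical run containing the offset (which the slide window recovers).
  No conversion tracts or junction indels. A `forced_block` option rewrites
  copy B locally so the identical block has an exact requested length
  (bounded by forced mismatches), used to sweep microhomology 0–60 bp in
  tests.
- **Junction reads.** Long error-free Sanger-like fragments (default 400 bp
  flanks; optional substitution noise up to 10%), not short-read pairs.
- **Pedigrees.** Affecteds homozygous for the founder haplotype at every
  marker (IBD, no recombination events modelled); carriers heterozygous
  founder/non-founder (the non-founder draw excludes the founder allele so
  carrier heterozygosity is guaranteed); null mode draws all alleles
  independently. Default: 10 families, 1 affected + 2 carriers each, founder
  haplotype (129, 188), two-marker panel with realistic 4-allele frequency
  tables.
- **Determinism.** All randomness flows from one seed through four spawned,
  independent streams (background, repeat mutation, junction read,
  pedigree), so changing one plan leaves the other outputs byte-identical.

What passing simulator-based tests shows — and does not. The simulator
emulates the *structure* that the analyses exploit (repeat homology,
microhomology at a clean junction, IBD homozygosity); it does not emulate
alignment-breaking indel divergence between repeat copies, sequencing
quality decay, allele dropout, microsatellite stutter, or recombination
between marker and locus. Exact recovery on simulated data therefore
validates the arithmetic and the inference logic, not robustness to those
real-data artifacts.

## Pipeline

One YAML config with CLI flag overrides (flags > config > defaults). Stage
outputs are written atomically (temp file + rename); logs go to stderr,
machine outputs only to files; the report stage re-reads stage files rather
than recomputing, so report numbers cannot drift from stage outputs.
Re-running with unchanged inputs and seed is byte-identical.

## Problem sizes in the test suite

The default suite simulates at the package's natural scale: 9358 bp loci,
200 simulated crossover deletions (lengths 0.5–6 kb, microhomology 0–60 bp)
for breakpoint-recovery properties, 60 random template/primer cases for the
PCR oracle, and 1000–1200 pedigree replicates for the null-model check —
sizes at which every oracle comparison is exhaustive or closed-form and the
whole suite runs in seconds.

## Known limitations

- Single contiguous deletions only: no multi-deletion, inversion or
  insertion junction resolution, and no read-level SV calling.
- Repeat detection itself (RepeatMasker's job) is out of scope; the package
  consumes annotations or simulator truth.
- Primer design and thermodynamics are out of scope; given panels are used
  as-is.
- No linkage LOD computation or haplotype dating; founder support is
  presence/absence sharing, not a likelihood.
- Accession-dependent checks (RefSeqGene product sizes, the published 35 bp
  junction overlap) require the NG_009252.1 sequence and run only when it is
  locally cached or fetchable.
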