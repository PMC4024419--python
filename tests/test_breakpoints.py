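"""Junction mapping, microhomology arithmetic, HGVS descriptions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aludel import (
    GenomicInterval,
    apply_deletion,
    c_deletion_length,
    map_deletion_junction,
    microhomology_length,
    normalize_3prime,
    parse_hgvs_c,
    parse_hgvs_g,
    to_hgvs_g,
)
from aludel.breakpoints import (
    AmbiguousAnchorError,
    InconsistentJunctionError,
    NoDeletionError,
    call_to_vcf,
    deletion_call,
    placement_window,
)
from aludel.hgvs import Exon, ExonMap, HgvsParseError

BASES = np.array(list("ACGT"))


def _random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def _brute_force_window(ref, start, end):
    """O(n*m) slide oracle: all placements whose mutant sequence equals the
    mutant of [start, end)."""
    d = end - start
    target = ref[:start] + ref[end:]
    return [s for s in range(len(ref) - d + 1) if ref[:s] + ref[s + d :] == target]


class TestMapping:
    def test_toy_clean_deletion(self):
        call = map_deletion_junction("AAAATTTTCCCC", "AAAACCCC", anchor_k=4)
        assert call.length == 4
        assert call.mh_len == 0
        assert (call.deletion.start, call.deletion.end) == (4, 8)
        assert call.ambiguity.length() == 1

    def test_junction_equal_to_reference_is_no_deletion(self):
        ref = "ACGTACGGTCAGGCTATTACGGATCGTTAACGGCTA"
        with pytest.raises(NoDeletionError):
            map_deletion_junction(ref, ref, anchor_k=10)

    def test_repeated_anchor_is_ambiguous(self):
        block = "ACGTACGTACGT"
        tail = "GGCCTTAAGGAATTCC"
        ref = block + "TTTTGGGGCCCCAAAA" + block + tail
        with pytest.raises(AmbiguousAnchorError):
            map_deletion_junction(ref, block + tail, anchor_k=12)

    def test_foreign_insertion_is_inconsistent(self):
        rng = np.random.default_rng(11)
        ref = _random_seq(rng, 400)
        junction = ref[:100] + "TTTTTTTTTTTTTTTTTTTT" + ref[300:]
        with pytest.raises(InconsistentJunctionError):
            map_deletion_junction(ref, junction, anchor_k=25)

    def test_recovers_random_planted_deletions(self):
        """Across seeded random deletions the recovered length is exact and
        the microhomology matches the brute-force slide oracle."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(500, 2500))
            ref = _random_seq(rng, n)
            start = int(rng.integers(60, n // 2))
            d = int(rng.integers(20, n - start - 60))
            end = start + d
            junction = apply_deletion(ref, GenomicInterval("r", start, end))
            call = map_deletion_junction(ref, junction, anchor_k=25)
            assert call.length == d
            placements = _brute_force_window(ref, start, end)
            assert call.mh_len == len(placements) - 1
            assert call.ambiguity.start == placements[0]
            assert start in range(call.ambiguity.start, call.ambiguity.end)

    def test_junction_reconstruction_for_every_placement(self, default_sim):
        """Removing the call's deletion at any placement in the ambiguity
        window reproduces the deleted allele exactly."""
        sim = default_sim
        call = map_deletion_junction(sim.reference, sim.junction_read)
        for s in range(call.ambiguity.start, call.ambiguity.end):
            mutant = sim.reference[:s] + sim.reference[s + call.length :]
            assert mutant == sim.deleted_allele

    def test_error_tolerant_extension(self):
        rng = np.random.default_rng(23)
        ref = _random_seq(rng, 800)
        junction = apply_deletion(ref, GenomicInterval("r", 300, 500))
        # corrupt one base well inside the left flank
        j = list(junction)
        j[150] = {"A": "C", "C": "G", "G": "T", "T": "A"}[j[150]]
        junction = "".join(j)
        call = map_deletion_junction(ref, junction, anchor_k=25, max_mismatches=2)
        assert call.length == 200


class TestMicrohomologySlide:
    def test_repeat_unit_microhomology(self):
        # deleting one GCT of AAGCTGCTTT can slide across the other copy
        assert microhomology_length("AAGCTGCTTT", GenomicInterval("r", 2, 5)) == 3

    def test_nonmatching_flanks_have_zero(self):
        assert microhomology_length("AAAATTTTCCCC", GenomicInterval("r", 4, 8)) == 0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            microhomology_length("ACGT", GenomicInterval("r", 2, 8))

    def test_normalize_shifts_to_most_3prime(self):
        norm = normalize_3prime("AAGCTGCTTT", GenomicInterval("r", 2, 5))
        assert (norm.start, norm.end) == (5, 8)
        again = normalize_3prime("AAGCTGCTTT", norm)
        assert again == norm  # idempotent

    def test_non_slidable_deletion_unchanged(self):
        iv = GenomicInterval("r", 4, 8)
        assert normalize_3prime("AAAATTTTCCCC", iv) == iv

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_matches_brute_force(self, seed):
        """placement_window agrees with exhaustive string-equality search and
        every placement inside (and none outside) yields the same mutant."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        ref = _random_seq(rng, n)
        start = int(rng.integers(0, n - 2))
        end = int(rng.integers(start + 1, min(n, start + 20) + 1))
        lo, hi = placement_window(ref, start, end)
        placements = _brute_force_window(ref, start, end)
        assert placements == list(range(lo, hi + 1))
        norm = normalize_3prime(ref, GenomicInterval("r", start, end))
        assert norm.start == hi
        mutant = ref[:start] + ref[end:]
        assert ref[: norm.start] + ref[norm.end :] == mutant


class TestHgvs:
    def test_published_abstract_description_is_consistent(self):
        d = parse_hgvs_g("NG_009252.1:g.36847_40771del3925")
        assert (d.start, d.end) == (36847, 40771)
        assert d.implied_length == 3925
        assert d.consistent

    def test_alternative_published_coordinates_also_internally_consistent(self):
        # a second printed coordinate pair for the same event; each pair is
        # internally consistent though they disagree with each other
        d = parse_hgvs_g("NG_009252.1:g.32438_36363del3926")
        assert d.implied_length == 3926
        assert d.consistent

    def test_length_suffix_mismatch_is_reported_not_corrected(self):
        d = parse_hgvs_g("REF:g.100_199del50")
        assert d.implied_length == 100
        assert not d.consistent
        assert d.stated_length == 50

    @given(
        st.text(alphabet=st.characters(whitelist_categories=("Lu", "Nd")), min_size=1, max_size=8),
        st.integers(1, 10**7),
        st.integers(0, 10**5),
        st.booleans(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_format_parse_roundtrip(self, ref, start, span, with_suffix):
        end = start + span
        text = to_hgvs_g(ref, start, end, end - start + 1 if with_suffix else None)
        d = parse_hgvs_g(text)
        assert (d.ref_name, d.start, d.end) == (ref, start, end)
        assert to_hgvs_g(d.ref_name, d.start, d.end, d.stated_length) == text

    @pytest.mark.parametrize("bad", ["g.1_2del", "REF:g.5_2del", "REF:g.x_2del", "REF:c.1_2del"])
    def test_parse_errors(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_g(bad)

    def test_cdna_description_parses_with_offsets(self):
        d = parse_hgvs_c("c.1370-2567_1539+1188del3925")
        assert (d.start_exon_pos, d.start_offset) == (1370, -2567)
        assert (d.end_exon_pos, d.end_offset) == (1539, 1188)
        assert d.stated_length == 3925


class TestCdnaLength:
    def test_single_exon_deletion_with_intronic_offsets(self):
        """The whole-exon deletion c.1370-2567_1539+1188 spans
        2567 + 170 + 1188 = 3925 genomic bases."""
        exon10 = Exon(1370, 1539, GenomicInterval("ref", 20000, 20170))
        d = parse_hgvs_c("c.1370-2567_1539+1188del3925")
        assert c_deletion_length(d, ExonMap([exon10])) == 3925

    def test_zero_offsets_give_exon_length(self):
        exon = Exon(1, 170, GenomicInterval("ref", 1000, 1170))
        d = parse_hgvs_c("c.1_170del")
        assert c_deletion_length(d, ExonMap([exon])) == 170

    def test_random_exon_maps_match_coordinate_resolution(self):
        """On multi-exon maps the result equals g_end - g_start + 1 computed
        from independently resolved genomic coordinates."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n_ex = int(rng.integers(1, 5))
            exons, c0, g0 = [], 1, int(rng.integers(1000, 5000))
            genomic_of = {}
            for _e in range(n_ex):
                L = int(rng.integers(50, 300))
                exons.append(Exon(c0, c0 + L - 1, GenomicInterval("ref", g0 - 1, g0 - 1 + L)))
                for i in range(L):
                    genomic_of[c0 + i] = g0 + i
                c0 += L
                g0 += L + int(rng.integers(100, 2000))  # next intron
            emap = ExonMap(exons)
            s = int(rng.integers(1, c0))
            e = int(rng.integers(s, c0))
            so = -int(rng.integers(0, 50)) if rng.random() < 0.5 else 0
            eo = int(rng.integers(0, 50)) if rng.random() < 0.5 else 0
            d = parse_hgvs_c(f"c.{s}{so if so else ''}_{e}{'+' + str(eo) if eo else ''}del")
            expect = (genomic_of[e] + eo) - (genomic_of[s] + so) + 1
            assert c_deletion_length(d, emap) == expect

    def test_endpoint_outside_transcript_rejected(self):
        emap = ExonMap([Exon(1, 100, GenomicInterval("ref", 0, 100))])
        with pytest.raises(HgvsParseError):
            c_deletion_length(parse_hgvs_c("c.1_250del"), emap)

    def test_noncontiguous_cdna_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ExonMap([
                Exon(1, 100, GenomicInterval("ref", 0, 100)),
                Exon(150, 249, GenomicInterval("ref", 500, 600)),
            ])


class TestVcfExport:
    def test_vcf_fields_match_call(self, default_sim):
        sim = default_sim
        call = sim.truth_call
        vcf = call_to_vcf(call, sim.reference)
        row = [l for l in vcf.strip().splitlines() if not l.startswith("#")][0]
        chrom, pos, _, ref_base, alt, _, _, info = row.split("\t")
        assert chrom == call.ref_name and alt == "<DEL>"
        assert int(pos) == call.deletion.start  # base before the deletion
        assert ref_base == sim.reference[call.deletion.start - 1]
        fields = dict(kv.split("=") for kv in info.split(";"))
        assert int(fields["END"]) == call.deletion.end
        assert int(fields["HOMLEN"]) == call.mh_len
        assert int(fields["SVLEN"]) == -call.length
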