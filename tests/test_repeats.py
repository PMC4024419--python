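"""Repeat-table parsing, landscape summary, and pair nomination."""

import numpy as np
import pytest

from aludel import (
    GenomicInterval,
    RepeatFeature,
    RepeatTable,
    find_recombinogenic_pairs,
    parse_rm_out,
    summarize_repeats,
    write_rm_out,
)
from aludel.repeats import RepeatParseError, alignment_identity, features_to_bed


def _feature(start0, end0, name="AluTest", family="SINE/Alu", orient="+", eid=1,
             seq_id="region"):
    return RepeatFeature(
        sw_score=1000, pct_div=10.0, pct_del=0.0, pct_ins=0.0,
        query=GenomicInterval(seq_id, start0, end0), orientation=orient,
        repeat_name=name, class_family=family,
        repeat_begin=1, repeat_end=end0 - start0, repeat_left=0, element_id=eid,
    )


class TestParse:
    def test_known_row_fields(self, locus_table):
        """The AluSq2 row at 3081-3372 parses with 1-based -> half-open
        conversion, '+' orientation, and its linkage id."""
        f = next(f for f in locus_table if f.query.start == 3080)
        assert f.repeat_name == "AluSq2"
        assert f.class_family == "SINE/Alu"
        assert (f.query.start, f.query.end) == (3080, 3372)
        assert f.query.to_1based() == (3081, 3372)
        assert f.orientation == "+" and f.strand == "+"
        assert f.sw_score == 2287 and f.element_id == 7
        assert (f.repeat_begin, f.repeat_end, f.repeat_left) == (1, 308, 5)

    def test_complement_row_repeat_coordinates(self, locus_table):
        """'C' rows carry their repeat coordinates in (left) end begin order."""
        f = next(f for f in locus_table if f.query.start == 656)  # AluJr
        assert f.orientation == "C" and f.strand == "-"
        assert (f.repeat_left, f.repeat_end, f.repeat_begin) == (2, 310, 74)

    def test_region_inferred_from_left_column(self, locus_table):
        assert locus_table.region.length() == 9358
        assert len(locus_table) == 19

    def test_empty_stream(self):
        assert len(parse_rm_out("")) == 0

    def test_roundtrip_identity(self, locus_table, default_sim):
        """parse(write(t)) preserves the feature list on both the packaged
        table and simulator truth tables."""
        for table in (locus_table, default_sim.repeat_table):
            again = parse_rm_out(write_rm_out(table))
            assert again.features == table.features
            assert again.region.length() == table.region.length()

    @pytest.mark.parametrize(
        "row, message",
        [
            ("100 1.0 1.0 1.0 q xx 200 (100) + Alu SINE/Alu 1 100 (0) 1", "line 1"),
            ("100 1.0 1.0 1.0 q 50 200 (100) ? Alu SINE/Alu 1 100 (0) 1", "orientation"),
            ("100 1.0 1.0 1.0 q 300 200 (100) + Alu SINE/Alu 1 100 (0) 1", "end"),
            ("100 1.0 1.0 1.0 q 50 200", "columns"),
        ],
    )
    def test_malformed_rows(self, row, message):
        with pytest.raises(RepeatParseError, match=message):
            parse_rm_out(row)


class TestSummary:
    def test_locus_fixture_landscape(self, locus_table):
        """The packaged 9358 bp window: 11 Alu elements over 2908 bp, 3 LINE
        elements over 1789 bp (fragment ids collapse the L1MB8 rows), and
        4814 bp = 51.44% interspersed repeats overall."""
        s = summarize_repeats(locus_table)
        assert s.region_length == 9358
        alu = s.by_family["SINE/Alu"]
        assert (alu.covered_bp, alu.element_count, alu.fraction) == (2908, 11, 31.08)
        line = s.by_class["LINE"]
        assert (line.covered_bp, line.element_count, line.fraction) == (1789, 3, 19.12)
        assert s.interspersed_bp == 4814
        assert s.interspersed_fraction == 51.44

    def test_single_full_length_feature(self):
        t = RepeatTable(GenomicInterval("r", 0, 250), (_feature(0, 250),))
        s = summarize_repeats(t)
        assert s.by_family["SINE/Alu"].fraction == 100.00
        assert s.interspersed_bp == 250

    def test_random_tables_match_per_base_bitmap(self):
        """Class coverages (merged) sum to the per-base occupancy union, and
        interspersed + simple/low-complexity coverage equals the union."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(200, 2000))
            feats = []
            classes = ["SINE/Alu", "LINE/L1", "Simple_repeat", "DNA/hAT"]
            for eid in range(1, int(rng.integers(2, 12))):
                s = int(rng.integers(0, n - 10))
                e = int(rng.integers(s + 1, min(n, s + 300)))
                feats.append(_feature(s, e, family=str(rng.choice(classes)), eid=eid))
            t = RepeatTable(GenomicInterval("region", 0, n), tuple(feats))
            summary = summarize_repeats(t)
            occupancy = np.zeros(n, dtype=bool)
            for f in feats:
                occupancy[f.query.start : f.query.end] = True
            # per-family bitmaps vs merged coverage
            for fam, cs in summary.by_family.items():
                bm = np.zeros(n, dtype=bool)
                for f in feats:
                    if f.class_family == fam:
                        bm[f.query.start : f.query.end] = True
                assert cs.covered_bp == int(bm.sum())
            assert summary.total_covered_bp == int(occupancy.sum())
            assert (
                summary.interspersed_bp + summary.simple_low_bp
                >= summary.total_covered_bp
            )  # equality unless simple repeats overlap interspersed ones

    def test_fragment_splitting_preserves_element_count(self, locus_table):
        """Splitting any feature into fragments sharing its linkage id leaves
        element counts unchanged (and coverage, for abutting fragments)."""
        s0 = summarize_repeats(locus_table)
        feats = []
        for f in locus_table:
            if f.query.length() > 40:
                mid = (f.query.start + f.query.end) // 2
                feats.append(
                    RepeatFeature(**{**vars(f), "query": GenomicInterval(
                        f.query.seq_id, f.query.start, mid)})
                )
                feats.append(
                    RepeatFeature(**{**vars(f), "query": GenomicInterval(
                        f.query.seq_id, mid, f.query.end)})
                )
            else:
                feats.append(f)
        s1 = summarize_repeats(RepeatTable(locus_table.region, tuple(feats)))
        for fam in s0.by_family:
            assert s0.by_family[fam].element_count == s1.by_family[fam].element_count
            assert s0.by_family[fam].covered_bp == s1.by_family[fam].covered_bp
        assert s1.interspersed_bp == s0.interspersed_bp

    def test_feature_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside region"):
            RepeatTable(GenomicInterval("r", 0, 100), (_feature(50, 150),))


class TestPairs:
    def test_single_repeat_yields_no_pairs(self):
        t = RepeatTable(GenomicInterval("r", 0, 500), (_feature(10, 110),))
        assert find_recombinogenic_pairs(t, "A" * 500, min_identity=50) == []

    def test_planted_identical_copies_rank_first(self):
        """Two identical planted copies give a 100% pair whose predicted
        deletion range brackets the equal-crossover deletion length."""
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        ref = "".join(bases[rng.integers(0, 4, 3000)])
        copy = "".join(bases[rng.integers(0, 4, 300)])
        ref = ref[:400] + copy + ref[700:1900] + copy + ref[2200:]
        feats = (
            _feature(400, 700, eid=1), _feature(1900, 2200, eid=2),
            _feature(1000, 1200, name="AluOther", eid=3),
        )
        t = RepeatTable(GenomicInterval("r", 0, 3000), feats)
        pairs = find_recombinogenic_pairs(t, ref, min_identity=90)
        assert pairs and pairs[0].identity == 100.0
        lo, hi = pairs[0].predicted_deletion_range
        assert lo <= 1900 - 400 <= hi  # equal-crossover length = start distance
        assert pairs[0].inter_repeat_distance == 1900 - 700

    def test_subfamily_exactness_and_relaxation(self, default_sim):
        """Exact subfamily matching separates AluSq2-type pairs from other
        Alus; relaxing to class/family admits cross-subfamily pairs."""
        sim = default_sim
        strict = find_recombinogenic_pairs(sim.repeat_table, sim.reference, 85.0, True)
        relaxed = find_recombinogenic_pairs(sim.repeat_table, sim.reference, 85.0, False)
        assert len(relaxed) >= len(strict)
        top = strict[0]
        assert top.a.repeat_name == top.b.repeat_name
        assert top.a.orientation == top.b.orientation
        # the simulator's crossover substrate pair is the top-ranked one
        assert top.a.query.start == 3080 and top.b.query.start == 6990

    def test_deterministic_ranking(self, default_sim):
        p1 = find_recombinogenic_pairs(default_sim.repeat_table, default_sim.reference, 80.0)
        p2 = find_recombinogenic_pairs(default_sim.repeat_table, default_sim.reference, 80.0)
        assert p1 == p2
        idents = [p.identity for p in p1]
        assert idents == sorted(idents, reverse=True)

    def test_length_mismatch_rejected(self, default_sim):
        with pytest.raises(ValueError, match="length"):
            find_recombinogenic_pairs(default_sim.repeat_table, "ACGT" * 10)


def test_alignment_identity_basics():
    assert alignment_identity("ACGTACGT", "ACGTACGT") == 100.0
    assert alignment_identity("ACGTACGT", "ACGAACGT") == pytest.approx(87.5)
    assert alignment_identity("", "ACGT") == 0.0


def test_bed_export(locus_table):
    lines = features_to_bed(locus_table).strip().splitlines()
    assert len(lines) == 19
    first = lines[0].split("\t")
    assert first[1:3] == ["656", "893"] and first[5] == "-"
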