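"""Submission parsing, name matching, and performance metrics."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virotrial import score
from virotrial.score import (
    AccessionResolver,
    AmbiguousPatternError,
    ExpectedVirusPattern,
    MetricsFormatError,
    VirusMetricsRow,
    builtin_patterns,
    depth_of_coverage,
    fp_families,
    match_expected,
    parse_metrics,
    resolve_name,
    sample_mean_depth,
    score_sample,
)

CMV = ExpectedVirusPattern(
    "Human betaherpesvirus 5", (r"betaherpesvirus 5", r"HHV-?5", r"CMV"), "Herpesviridae"
)
HSV1 = ExpectedVirusPattern(
    "Human alphaherpesvirus 1", (r"alphaherpesvirus 1", r"HSV-?1"), "Herpesviridae"
)

RESOLVER = AccessionResolver(
    {
        "ACC_CMV1": ("Human betaherpesvirus 5 strain AD169", "Human betaherpesvirus 5", "Herpesviridae"),
        "ACC_CMV2": ("Human herpesvirus 5 isolate CMV-x", "Human betaherpesvirus 5", "Herpesviridae"),
        "ACC_HSV": ("Human alphaherpesvirus 1 strain KOS", "Human alphaherpesvirus 1", "Herpesviridae"),
        "ACC_TTV": ("Torque teno virus isolate t1", "Torque teno virus", "Anelloviridae"),
        "ACC_JC": ("JC polyomavirus strain Mad1", "JC polyomavirus", "Polyomaviridae"),
        "ACC_BK": ("BK polyomavirus strain Dunlop", "BK polyomavirus", "Polyomaviridae"),
    }
)


def row(acc, reads=1000, report=1, coverage=75.0, size=150000, comment=""):
    return VirusMetricsRow(
        virus="x", database_id=acc, number_of_reads=reads,
        percent_coverage=coverage, genome_size=size, report=report, comment=comment,
    )


class TestParseMetrics:
    CSV = (
        "Virus,database_ID,Number_of_reads,percent_coverage,genome_size,Report,comment\n"
        "CMV,ACC_CMV1,1200,88.5,235000,1,\n"
        "HSV,ACC_HSV,40,12.0,152000,0,low coverage\n"
        "TTV,ACC_TTV,9,1.0,3800,1,\n"
    )

    def test_well_formed_csv(self):
        res = parse_metrics(io.StringIO(self.CSV))
        assert len(res.rows) == 3 and res.errors == ()
        assert res.rows[0].database_id == "ACC_CMV1"
        assert res.rows[1].report == 0

    def test_header_aliases_case_and_spacing(self):
        csv = (
            "virus,Database ID,number of reads,Percent_Coverage,Genome Size,report\n"
            "CMV,ACC_CMV1,10,5.0,235000,1\n"
        )
        res = parse_metrics(io.StringIO(csv))
        assert res.rows[0].percent_coverage == 5.0
        assert res.rows[0].genome_size == 235000

    def test_tab_separated_accepted(self):
        res = parse_metrics(io.StringIO(self.CSV.replace(",", "\t")))
        assert len(res.rows) == 3

    def test_missing_report_column_uses_supplied_list(self):
        csv = (
            "Virus,database_ID,Number_of_reads,percent_coverage,genome_size\n"
            "CMV,ACC_CMV1,10,5.0,235000\n"
            "HSV,ACC_HSV,10,5.0,152000\n"
            "TTV,ACC_TTV,10,5.0,3800\n"
        )
        res = parse_metrics(io.StringIO(csv), report_accessions=["ACC_CMV1", "ACC_TTV"])
        assert [r.report for r in res.rows] == [1, 0, 1]

    def test_missing_report_without_list_is_format_error(self):
        csv = "Virus,database_ID,Number_of_reads,percent_coverage,genome_size\nx,A,1,1,10\n"
        with pytest.raises(MetricsFormatError, match="report"):
            parse_metrics(io.StringIO(csv))

    def test_unrecognizable_headers_listed(self):
        with pytest.raises(MetricsFormatError, match="number_of_reads"):
            parse_metrics(io.StringIO("Virus,database_ID,foo\nx,A,1\n"))

    def test_uninterpretable_comment_forces_not_reported(self):
        csv = (
            "Virus,database_ID,Number_of_reads,percent_coverage,genome_size,Report,comment\n"
            "CMV,ACC_CMV1,10,5.0,235000,1,Uninterpretable signal\n"
            "HSV,ACC_HSV,10,5.0,152000,1,cannot be excluded\n"
            "TTV,ACC_TTV,10,5.0,3800,1,clear hit\n"
        )
        res = parse_metrics(io.StringIO(csv))
        assert [r.report for r in res.rows] == [0, 0, 1]

    def test_malformed_rows_logged_not_dropped_silently(self):
        csv = (
            "Virus,database_ID,Number_of_reads,percent_coverage,genome_size,Report\n"
            "ok,ACC_CMV1,10,5.0,235000,1\n"
            "bad,ACC_HSV,not_a_number,5.0,152000,1\n"
            "bad2,ACC_TTV,10,140.0,3800,1\n"
        )
        res = parse_metrics(io.StringIO(csv))
        assert len(res.rows) == 1
        assert sorted(e.row_index for e in res.errors) == [1, 2]


class TestNameResolution:
    def test_present_accession_resolves(self):
        r = resolve_name("ACC_CMV1", RESOLVER)
        assert r.name == "Human betaherpesvirus 5 strain AD169"
        assert r.family == "Herpesviridae"

    def test_absent_accession_marked_unresolved(self):
        r = resolve_name("NOPE_1", RESOLVER)
        assert r.name is None and r.accession == "NOPE_1"

    def test_fixture_world_roundtrip(self, small_world):
        resolver = small_world.resolver()
        acc = small_world.records[0].accession
        assert resolve_name(acc, resolver).name == small_world.taxonomy[acc].name


class TestMatchExpected:
    def test_strain_name_matches_synonyms(self):
        assert (
            match_expected("Human betaherpesvirus 5 strain AD169", [CMV, HSV1])
            == "Human betaherpesvirus 5"
        )
        assert match_expected("human HERPESVIRUS, HHV-5 subtype", [CMV, HSV1]) == (
            "Human betaherpesvirus 5"
        )

    def test_absent_species_is_candidate_fp(self):
        assert match_expected("Torque teno virus", [CMV, HSV1]) is None

    def test_overlapping_patterns_raise_ambiguity(self):
        clash = ExpectedVirusPattern("Clash", (r"betaherpesvirus",), "X")
        with pytest.raises(AmbiguousPatternError):
            match_expected("Human betaherpesvirus 5", [CMV, clash])

    def test_builtin_pattern_sets(self):
        ii, iii = builtin_patterns("II"), builtin_patterns("III")
        assert len(ii) == 11 and len(iii) == 7
        assert match_expected("Human herpesvirus 5 (CMV) strain x", iii) == (
            "Human betaherpesvirus 5"
        )
        assert match_expected("Norovirus GII.4 Sydney", ii) == "Norwalk virus"


class TestScoreSample:
    EXPECTED = [CMV, HSV1]

    def test_all_found_no_fp_is_perfect(self):
        s = score_sample([row("ACC_CMV1"), row("ACC_HSV")], self.EXPECTED, RESOLVER)
        assert (s.tp, s.fp, s.fn) == (2, 0, 0)
        assert (s.sensitivity, s.precision, s.f1) == (1.0, 1.0, 1.0)

    def test_two_strains_of_one_species_single_tp(self):
        s = score_sample([row("ACC_CMV1"), row("ACC_CMV2")], self.EXPECTED, RESOLVER)
        assert s.tp == 1 and s.fp == 0 and s.fn == 1

    def test_unreported_rows_ignored(self):
        s = score_sample(
            [row("ACC_CMV1"), row("ACC_HSV", report=0)], self.EXPECTED, RESOLVER
        )
        assert s.tp == 1 and s.fn == 1

    def test_planted_5_5_5_gives_half_everything(self):
        expected = [
            ExpectedVirusPattern(f"Species {i:02d}", (f"Species {i:02d}",), "F")
            for i in range(10)
        ]
        resolver = AccessionResolver(
            {f"T{i}": (f"Species {i:02d} isolate x", f"Species {i:02d}", "F") for i in range(5)}
            | {f"D{i}": (f"Decoy {i:02d} isolate y", f"Decoy {i:02d}", "G") for i in range(5)}
        )
        rows = [row(f"T{i}") for i in range(5)] + [row(f"D{i}") for i in range(5)]
        s = score_sample(rows, expected, resolver)
        assert (s.tp, s.fn, s.fp) == (5, 5, 5)
        assert s.sensitivity == 0.5 and s.precision == 0.5 and s.f1 == 0.5

    def test_negative_sample_carries_fp_only(self):
        s = score_sample([row("ACC_TTV"), row("ACC_JC"), row("ACC_BK")], [], RESOLVER)
        assert s.fp == 3 and s.tp == 0 and s.fn == 0
        assert s.sensitivity is None and s.f1 is None
        assert s.fp_families == {"Anelloviridae": 1, "Polyomaviridae": 2}

    def test_zero_report_sample_undefined_precision_and_f1(self):
        s = score_sample([row("ACC_CMV1", report=0)], self.EXPECTED, RESOLVER)
        assert (s.tp, s.fn, s.fp) == (0, 2, 0)
        assert s.sensitivity == 0.0
        assert s.precision is None and s.f1 is None
        assert s.harmonic_mean_depth is None

    def test_unresolved_accession_counts_fp_with_warning(self):
        s = score_sample([row("MYSTERY_9")], self.EXPECTED, RESOLVER)
        assert s.fp == 1 and s.fp_families == {"unknown": 1}
        assert any("MYSTERY_9" in w for w in s.warnings)

    def test_conservation_tp_plus_fn(self):
        for rows in ([], [row("ACC_CMV1")], [row("ACC_CMV1"), row("ACC_TTV")]):
            s = score_sample(rows, self.EXPECTED, RESOLVER)
            assert s.tp + s.fn == len(self.EXPECTED)

    @given(
        tp=st.integers(0, 5), fn=st.integers(0, 5), fp=st.integers(0, 5)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_f1_between_sensitivity_and_precision(self, tp, fn, fp):
        expected = [
            ExpectedVirusPattern(f"Sp {i:02d}", (f"Sp {i:02d}",), "F")
            for i in range(tp + fn)
        ]
        resolver = AccessionResolver(
            {f"T{i}": (f"Sp {i:02d} x", f"Sp {i:02d}", "F") for i in range(tp)}
            | {f"D{i}": (f"Dx {i:02d} y", f"Dx {i:02d}", "G") for i in range(fp)}
        )
        rows = [row(f"T{i}") for i in range(tp)] + [row(f"D{i}") for i in range(fp)]
        s = score_sample(rows, expected, resolver)
        assert (s.tp, s.fn, s.fp) == (tp, fn, fp)
        if s.f1 is not None and s.sensitivity is not None and s.precision is not None:
            lo = min(s.sensitivity, s.precision)
            hi = max(s.sensitivity, s.precision)
            assert lo - 1e-12 <= s.f1 <= hi + 1e-12
            if s.sensitivity == s.precision:
                assert s.f1 == pytest.approx(s.sensitivity)


class TestDepth:
    @pytest.mark.parametrize(
        "reads, length, size, expected",
        [
            (0, 150, 30000, 0.0),
            (1000, 150, 30000, 5.0),
            (2000, 150, 235000, pytest.approx(1.2766, abs=1e-3)),
        ],
    )
    def test_depth_formula(self, reads, length, size, expected):
        assert depth_of_coverage(reads, length, size) == expected

    def test_nonpositive_genome_rejected(self):
        with pytest.raises(ValueError):
            depth_of_coverage(10, 150, 0)

    def test_depth_linearity(self):
        base = depth_of_coverage(500, 100, 40000)
        assert depth_of_coverage(1000, 100, 40000) == 2 * base
        assert depth_of_coverage(500, 200, 40000) == 2 * base
        assert depth_of_coverage(500, 100, 80000) == base / 2

    @pytest.mark.parametrize(
        "depths, expected",
        [([5.0, 5.0], 5.0), ([2.0, 8.0], 3.2), ([], None), ([4.0, 0.0], None)],
    )
    def test_harmonic_mean_depth(self, depths, expected):
        got = sample_mean_depth(depths)
        assert got == expected if expected is None else got == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0.01, max_value=1000), min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_harmonic_never_exceeds_arithmetic(self, depths):
        assert sample_mean_depth(depths) <= sum(depths) / len(depths) + 1e-9


class TestFpFamilies:
    def test_two_polyomaviruses(self):
        assert fp_families([row("ACC_JC"), row("ACC_BK")], RESOLVER) == {
            "Polyomaviridae": 2
        }

    def test_empty(self):
        assert fp_families([], RESOLVER) == {}

    def test_counts_sum_to_distinct_fp_identities(self):
        fams = fp_families(
            [row("ACC_JC"), row("ACC_BK"), row("ACC_TTV"), row("NOPE")], RESOLVER
        )
        assert sum(fams.values()) == 4
        assert set(fams) == {"Polyomaviridae", "Anelloviridae", "unknown"}


def test_pattern_file_roundtrip(tmp_path):
    pats = builtin_patterns("III")
    score.save_patterns(pats, tmp_path / "p.yaml")
    back = score.load_patterns(tmp_path / "p.yaml")
    assert back == pats
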