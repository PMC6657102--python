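"""Pack-year tier logic, cessation anchoring, and date normalization."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from smokereg.extraction import (
    CIGARETTES_PER_PACK,
    extract_cessation_date,
    extract_pack_years,
    normalize_date,
    render_date,
)


class TestPackYearTiers:
    def test_complete_short_circuits_lower_tiers(self, rules):
        finding = extract_pack_years("30 pack year history; currently 1 ppd", rules)
        assert finding.kind == "complete"
        assert finding.pack_years == 30.0
        assert finding.packs_per_day is None  # lower tiers never evaluated

    @pytest.mark.parametrize(
        "text,expected_py,expected_fields",
        [
            ("2 packs per day for 20 years", 40.0, {"packs_per_day": 2.0, "years_smoked": 20.0}),
            (
                "smokes 10 cigarettes a day for 10 years",
                5.0,
                {"cigarettes_per_day": 10.0, "years_smoked": 10.0},
            ),
            ("1 ppd x 20 yrs", 20.0, {"packs_per_day": 1.0, "years_smoked": 20.0}),
        ],
    )
    def test_computed_from_intensity_and_duration(self, rules, text, expected_py, expected_fields):
        finding = extract_pack_years(text, rules)
        assert finding.kind == "computed"
        assert finding.pack_years == expected_py
        for name, value in expected_fields.items():
            assert getattr(finding, name) == value

    @pytest.mark.parametrize(
        "text,field,value",
        [
            ("smokes about half a pack per day", "packs_per_day", 0.5),
            ("smokes a pack a day", "packs_per_day", 1.0),
            ("admits to 15 cigarettes per day", "cigarettes_per_day", 15.0),
            ("smoked for 25 years", "years_smoked", 25.0),
        ],
    )
    def test_partial_when_pack_years_not_determinable(self, rules, text, field, value):
        finding = extract_pack_years(text, rules)
        assert finding.kind == "partial"
        assert finding.pack_years is None
        assert getattr(finding, field) == value

    @pytest.mark.parametrize(
        "text",
        ["", "Patient feels well.", "BP 120/80, HR 72.", "CBC drawn 03/15/2010."],
    )
    def test_no_finding_without_rule_match(self, rules, text):
        assert extract_pack_years(text, rules) is None

    @pytest.mark.parametrize(
        "tail",
        ["2 packs per day for 20 years", "smokes 15 cigarettes per day", "smoked for 25 years", ""],
    )
    def test_adding_pack_year_expression_dominates_any_text(self, rules, tail):
        """Tier short-circuit: a pack-year expression makes lower tiers irrelevant."""
        finding = extract_pack_years(f"45 pack year history. {tail}", rules)
        assert finding.kind == "complete"
        assert finding.pack_years == 45.0

    def test_first_finding_in_document_order_wins(self, rules):
        finding = extract_pack_years("Pack years: 10. Also 60 pack year history?", rules)
        assert finding.pack_years == 10.0

    def test_source_span_resolves_into_text(self, rules):
        text = "Social history: 2 packs per day for 20 years, wants to quit."
        finding = extract_pack_years(text, rules)
        lo, hi = finding.source_span
        assert text[lo:hi] == finding.source_text


@given(
    ppd=st.sampled_from([0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]),
    years=st.integers(min_value=1, max_value=60),
)
def test_computed_arithmetic_from_packs_per_day(ppd, years):
    finding = extract_pack_years(f"smoked {ppd:g} packs per day for {years} years")
    assert finding.kind == "computed"
    assert finding.pack_years == round(ppd * years, 1)


@given(
    cpd=st.integers(min_value=1, max_value=60),
    years=st.integers(min_value=1, max_value=60),
)
def test_computed_arithmetic_converts_cigarettes_at_twenty_per_pack(cpd, years):
    finding = extract_pack_years(f"smoked {cpd} cigarettes a day for {years} years")
    assert finding.kind == "computed"
    assert finding.pack_years == round(cpd / CIGARETTES_PER_PACK * years, 1)


class TestCessation:
    @pytest.mark.parametrize(
        "text,date,precision",
        [
            ("quit smoking 03/15/2010", dt.date(2010, 3, 15), "day"),
            ("quit smoking 3/5/98", dt.date(1998, 3, 5), "day"),
            ("Patient quit July 4, 1999", dt.date(1999, 7, 4), "day"),
            ("Stopped smoking March 2008", dt.date(2008, 3, 1), "month"),
            ("quit tobacco in 1995", dt.date(1995, 1, 1), "year"),
            ("Tobacco free since 06/2012", dt.date(2012, 6, 1), "month"),
            ("quit in '95", dt.date(1995, 1, 1), "year"),
        ],
    )
    def test_cue_anchored_dates_normalize(self, rules, text, date, precision):
        finding = extract_cessation_date(text, rules)
        assert finding is not None
        assert (finding.date, finding.precision) == (date, precision)

    @pytest.mark.parametrize(
        "text",
        [
            "patient quit in the late 1980s",
            "quit sometime in the '90s",
            "quit between 1995 to 1998",
            "CBC drawn 03/15/2010; denies quitting",
            "Follow-up visit on 03/15/2010.",
            "quit smoking, date unknown",
            "",
        ],
    )
    def test_vague_unanchored_or_absent_dates_yield_nothing(self, rules, text):
        assert extract_cessation_date(text, rules) is None

    def test_date_in_other_sentence_not_anchored(self, rules):
        text = "Patient quit smoking. Labs drawn 03/15/2010."
        assert extract_cessation_date(text, rules) is None

    def test_cue_sentence_without_date_does_not_block_later_one(self, rules):
        text = "Patient quit smoking. Reports she stopped smoking March 2008."
        finding = extract_cessation_date(text, rules)
        assert finding.date == dt.date(2008, 3, 1)

    def test_source_span_resolves(self, rules):
        text = "SOCIAL HISTORY:\nQuit smoking 03/15/2010.\nFeels well."
        finding = extract_cessation_date(text, rules)
        lo, hi = finding.source_span
        assert text[lo:hi] == finding.source_text == "03/15/2010"


class TestNormalizeDate:
    @pytest.mark.parametrize(
        "expr,date,precision",
        [
            ("07/04/1999", dt.date(1999, 7, 4), "day"),
            ("7/4/99", dt.date(1999, 7, 4), "day"),
            ("7/4/05", dt.date(2005, 7, 4), "day"),
            ("July 4, 1999", dt.date(1999, 7, 4), "day"),
            ("Jul 4 1999", dt.date(1999, 7, 4), "day"),
            ("July 1999", dt.date(1999, 7, 1), "month"),
            ("03/2010", dt.date(2010, 3, 1), "month"),
            ("1995", dt.date(1995, 1, 1), "year"),
            ("'95", dt.date(1995, 1, 1), "year"),
            ("95", dt.date(1995, 1, 1), "year"),
        ],
    )
    def test_supported_formats(self, expr, date, precision):
        assert normalize_date(expr) == (date, precision)

    @pytest.mark.parametrize(
        "expr",
        [
            "the late 1980s",
            "1980s",
            "'80s",
            "1995-1998",
            "1995 to 1998",
            "spring 1999",
            "13/45/2010",
            "02/30/2010",
            "sometime",
            "",
        ],
    )
    def test_decades_ranges_seasons_and_junk_fail(self, expr):
        assert normalize_date(expr) is None

    def test_two_digit_pivot_over_all_years(self):
        """00-29 resolve to the 2000s, 30-99 to the 1900s, exhaustively."""
        for yy in range(100):
            date, precision = normalize_date(f"{yy:02d}")
            assert precision == "year"
            assert date.year == (2000 + yy if yy <= 29 else 1900 + yy)

    @given(
        year=st.integers(min_value=1930, max_value=2029),
        month=st.integers(min_value=1, max_value=12),
        day=st.integers(min_value=1, max_value=28),
        precision=st.sampled_from(["day", "month", "year"]),
    )
    def test_render_then_parse_round_trips(self, year, month, day, precision):
        if precision == "year":
            date = dt.date(year, 1, 1)
        elif precision == "month":
            date = dt.date(year, month, 1)
        else:
            date = dt.date(year, month, day)
        assert normalize_date(render_date(date, precision)) == (date, precision)
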