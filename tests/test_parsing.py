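import pytest
from hypothesis import given, settings, strategies as st

from treatkit import (
    ValidationError,
    bin_elevation,
    compose_sex_text,
    parse_event_date,
    parse_sex_field,
    reconcile_counts,
    split_collectors,
)
from treatkit.parsing import SexFieldParse


@pytest.mark.parametrize(
    "text, males, females, other, unparsed",
    [
        ("1 male, 4 females", 1, 4, 0, []),
        ("", 0, 0, 0, []),
        (None, 0, 0, 0, []),
        ("110 males, 44 females", 110, 44, 0, []),
        ("2 ♂, 1 juv., 1 sp.", 2, 0, 1, ["1 sp."]),
        ("male and female", 1, 1, 0, []),
        ("3 Females; 2 subadults", 0, 3, 2, []),
        ("1 ♀, 2 imm.", 0, 1, 2, []),
    ],
)
def test_sex_field_grammar(text, males, females, other, unparsed):
    parse = parse_sex_field(text)
    assert (parse.males, parse.females, parse.stated_other) == (males, females, other)
    assert parse.unparsed_tokens == unparsed


@given(
    males=st.integers(0, 500),
    females=st.integers(0, 500),
    other=st.integers(0, 100),
)
@settings(derandomize=True, max_examples=100)
def test_sex_field_parse_is_idempotent_on_rendered_text(males, females, other):
    """Rendering counts and re-parsing the text returns the same counts."""
    text = compose_sex_text(males, females, other)
    parse = parse_sex_field(text)
    assert (parse.males, parse.females, parse.stated_other) == (males, females, other)
    assert parse.unparsed_tokens == []


@pytest.mark.parametrize(
    "stated, individual_count, expected, warns",
    [
        ((1, 4, 0), 5, (1, 4, 0, 5), False),
        ((1, 4, 0), 7, (1, 4, 2, 7), False),  # surplus goes to "other"
        ((1, 4, 0), None, (1, 4, 0, 5), False),
        ((2, 2, 1), 3, (2, 2, 1, 5), True),  # understated count: keep the larger
        ((0, 0, 0), 0, (0, 0, 0, 0), False),
        ((0, 0, 0), 12, (0, 0, 12, 12), False),
    ],
)
def test_reconcile_counts(stated, individual_count, expected, warns):
    parse = SexFieldParse(*stated)
    counts, warning = reconcile_counts(parse, individual_count)
    assert (counts.males, counts.females, counts.other, counts.total) == expected
    assert (warning is not None) is warns


def test_reconcile_rejects_negative_individual_count():
    with pytest.raises(ValidationError):
        reconcile_counts(SexFieldParse(1, 0, 0), -1)


@given(
    males=st.integers(0, 50),
    females=st.integers(0, 50),
    other=st.integers(0, 50),
    ic=st.one_of(st.none(), st.integers(0, 200)),
)
@settings(derandomize=True, max_examples=200)
def test_reconcile_never_loses_specimens(males, females, other, ic):
    counts, _ = reconcile_counts(SexFieldParse(males, females, other), ic)
    assert counts.total >= males + females
    assert counts.other >= 0
    assert counts.total == counts.males + counts.females + counts.other


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Y. M. Marusik & D. V. Obydov", ["Y. M. Marusik", "D. V. Obydov"]),
        ("Y. M. Marusik", ["Y. M. Marusik"]),
        ("Kuntner, Gregoric, Candek", ["Kuntner", "Gregoric", "Candek"]),
        ("A and B; C", ["A", "B", "C"]),
        ("", []),
        (None, []),
    ],
)
def test_split_collectors(raw, expected):
    assert split_collectors(raw) == expected


def test_collector_order_is_preserved():
    ab = split_collectors("A & B")
    ba = split_collectors("B & A")
    assert ab == ["A", "B"] and ba == ["B", "A"] and ab != ba


@pytest.mark.parametrize(
    "text, year, month, day, decade",
    [
        ("1999-07-15", 1999, 7, 15, 1990),
        ("1999-07", 1999, 7, None, 1990),
        ("2014", 2014, None, None, 2010),
        ("15.07.1999", 1999, 7, 15, 1990),
        ("15 Jul 1999", 1999, 7, 15, 1990),
        ("3 September 1987", 1987, 9, 3, 1980),
        ("12–15 Jul 1999", 1999, 7, 12, 1990),  # range: start date used
        ("12-15 Jul 1999", 1999, 7, 12, 1990),
    ],
)
def test_event_date_grammar(text, year, month, day, decade):
    date = parse_event_date(text)
    assert date is not None
    assert (date.year, date.month, date.day) == (year, month, day)
    assert date.decade == decade
    assert date.decade_label == f"{decade}s"


@pytest.mark.parametrize("text", ["summer 1999", "1999-13", "32 Jul 1999", "no date", ""])
def test_unparseable_dates_return_none(text):
    assert parse_event_date(text) is None


@pytest.mark.parametrize(
    "elevation, label",
    [
        (4200, "4,001–4,500"),
        (1500, "1,001–1,500"),  # upper bound is inclusive
        (1, "1–500"),
        (0, "1–500"),
        (501, "501–1,000"),
        (9000, "8,501–9,000"),
    ],
)
def test_elevation_bands(elevation, label):
    band = bin_elevation(elevation)
    assert band.label == label
    assert band.upper_m == band.lower_m + 500


@pytest.mark.parametrize("elevation", [-1, 9001])
def test_out_of_range_elevation_rejected(elevation):
    with pytest.raises(ValidationError):
        bin_elevation(elevation)


@given(st.integers(1, 9000))
@settings(derandomize=True, max_examples=300)
def test_bands_tile_without_overlap(elevation):
    """Every elevation maps to exactly one band containing it."""
    band = bin_elevation(elevation)
    assert band.lower_m < elevation <= band.upper_m
    assert band.lower_m % 500 == 0
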