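"""Unit-cost derivations and the four-table CSV schema."""

from decimal import Decimal
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmccost.inventory import (ContactEvent, DrugCourse, InventoryParseError,
                               StaffRole, contact_cost, drug_course_cost,
                               loaded_annual_cost, per_minute_cost,
                               read_inventory_csv, write_inventory_csv)
from rmccost.money import MoneyEUR, ValidationError
from rmccost.synthetic import fixture_paths

# ---------------------------------------------------------------------------
# salary loading and per-minute rates
# ---------------------------------------------------------------------------

def test_loaded_annual_cost_zero_rates_is_identity():
    assert loaded_annual_cost(100_000, 0, 0, 0) == Decimal(100_000)


def test_loaded_annual_cost_standard_oncosts():
    # 100000 x 1.1505 x 1.25, by hand
    assert loaded_annual_cost(100_000, 0.1105, 0.04, 0.25) == Decimal("143812.50")


@pytest.mark.parametrize("kwargs", [
    dict(base_salary=-1, prsi_rate=0, pension_rate=0, overhead_rate=0),
    dict(base_salary=1, prsi_rate=1.2, pension_rate=0, overhead_rate=0),
    dict(base_salary=1, prsi_rate=0, pension_rate=-0.1, overhead_rate=0),
])
def test_loaded_annual_cost_validation(kwargs):
    with pytest.raises(ValidationError):
        loaded_annual_cost(**kwargs)


@pytest.mark.parametrize("annual,expected", [
    (Decimal("121680"), Decimal("1.00")),
    (Decimal("93693.60"), Decimal("0.77")),    # published midwife rate
    (Decimal("362606.40"), Decimal("2.98")),   # published obstetrician rate
])
def test_per_minute_cost_at_39h_52wk(annual, expected):
    assert per_minute_cost(annual, 39, 52) == expected


def test_per_minute_cost_rejects_zero_denominator():
    with pytest.raises(ValidationError):
        per_minute_cost(100, 0, 52)
    with pytest.raises(ValidationError):
        per_minute_cost(100, 39, 0)


def test_per_minute_rate_back_solves_loaded_annual():
    # loaded annual implied by €0.77/min at 39 h/wk, 52 wk/yr
    assert Decimal("0.77") * 39 * 60 * 52 == Decimal("93693.60")


@given(st.integers(min_value=1, max_value=300_000),
       st.integers(min_value=0, max_value=100))
@settings(deadline=None)
def test_loaded_cost_monotone_in_rates(salary, rate_pct):
    rate = Decimal(rate_pct) / 100
    base = loaded_annual_cost(salary, 0, 0, 0)
    assert loaded_annual_cost(salary, rate, 0, 0) >= base
    assert loaded_annual_cost(salary, 0, rate, 0) >= base
    assert loaded_annual_cost(salary, 0, 0, rate) >= base


# ---------------------------------------------------------------------------
# staff contact costing
# ---------------------------------------------------------------------------

@pytest.fixture
def obstetrician():
    return StaffRole("obstetrician", Decimal("2.98"))


@pytest.fixture
def midwife():
    return StaffRole("bereavement_midwife", Decimal("0.77"))


def test_contact_cost_typical_consultation(obstetrician):
    cost = contact_cost(ContactEvent(obstetrician, minutes=30))
    assert cost == MoneyEUR.parse("89.40")
    assert cost.present_euros() == 89


def test_contact_cost_midwife_hour(midwife):
    cost = contact_cost(ContactEvent(midwife, minutes=60))
    assert cost == MoneyEUR.parse("46.20")
    assert cost.present_euros() == 46


def test_contact_cost_scales_with_count(obstetrician):
    one = contact_cost(ContactEvent(obstetrician, 30, count=1))
    three = contact_cost(ContactEvent(obstetrician, 30, count=3))
    assert three == one * 3


def test_zero_contacts_disallowed(obstetrician):
    with pytest.raises(ValidationError):
        ContactEvent(obstetrician, minutes=30, count=0)
    with pytest.raises(ValidationError):
        ContactEvent(obstetrician, minutes=0, count=1)


# ---------------------------------------------------------------------------
# drug-course costing
# ---------------------------------------------------------------------------

def _course(weeks, price, cover, policy="prorata", printed=None):
    return DrugCourse(name="d", dose_label="x", duration_weeks=weeks,
                      pack_price=MoneyEUR.parse(price), pack_cover_days=cover,
                      pack_policy=policy,
                      printed_cost=MoneyEUR.parse(printed) if printed else None)


def test_prorata_heparin_course():
    # 34 weeks on a 10-day pack: 238/10 packs x €98.20
    assert drug_course_cost(_course(34, "98.20", 10)) == MoneyEUR.parse("2337.16")


def test_prorata_aspirin_course_quantizes_half_up():
    # 231/28 packs x €3.10 = 25.575 -> €25.58, presents €26
    cost = drug_course_cost(_course(33, "3.10", 28))
    assert cost == MoneyEUR.parse("25.58")
    assert cost.present_euros() == 26


def test_one_pack_identity():
    assert drug_course_cost(_course(4, "12.34", 28)) == MoneyEUR.parse("12.34")


def test_printed_override_verbatim():
    assert drug_course_cost(_course(36, "7.66", 30, "printed_override", "65.11")) \
        == MoneyEUR.parse("65.11")


def test_printed_override_requires_cost():
    with pytest.raises(ValidationError):
        _course(36, "7.66", 30, "printed_override")


@given(weeks=st.integers(min_value=1, max_value=60),
       price_cents=st.integers(min_value=1, max_value=20_000),
       cover=st.integers(min_value=1, max_value=60))
@settings(deadline=None, max_examples=300)
def test_prorata_never_exceeds_whole_pack(weeks, price_cents, cover):
    price = MoneyEUR(price_cents)
    pro = drug_course_cost(_course(weeks, price.euros, cover))
    whole = drug_course_cost(_course(weeks, price.euros, cover, "ceil_whole_pack"))
    assert pro <= whole
    if (weeks * 7) % cover == 0:
        assert pro == whole


@given(weeks=st.integers(min_value=1, max_value=30),
       price_cents=st.integers(min_value=1, max_value=10_000))
@settings(deadline=None, max_examples=200)
def test_prorata_linear_in_duration_when_exact(weeks, price_cents):
    # with a 7-day pack, packs = weeks exactly: cost must be weeks x price
    price = MoneyEUR(price_cents)
    assert drug_course_cost(_course(weeks, price.euros, 7)) == price * weeks


# ---------------------------------------------------------------------------
# CSV read/write
# ---------------------------------------------------------------------------

def _table_paths():
    p = fixture_paths()
    return {k: p[k] for k in ("investigations", "treatments", "staff", "program")}


def test_fixture_has_thirteen_investigations():
    inv = read_inventory_csv(_table_paths())
    assert len(inv.investigations) == 13


def test_empty_investigations_table(tmp_path):
    paths = dict(_table_paths())
    empty = tmp_path / "investigations.csv"
    empty.write_text("name,unit_cost_eur,typical,complex\n")
    paths["investigations"] = empty
    inv = read_inventory_csv(paths)
    assert inv.investigations == ()


def test_round_trip_is_identity(tmp_path):
    inv = read_inventory_csv(_table_paths())
    out = {k: tmp_path / f"{k}.csv" for k in ("investigations", "treatments", "staff", "program")}
    write_inventory_csv(inv, out)
    again = read_inventory_csv(out)
    assert again == inv


@pytest.mark.parametrize("mutation,match", [
    (lambda text: text.replace("unit_cost_eur", "cost"), "missing column"),
    (lambda text: text.replace("20.00,1,1", "twenty,1,1"), "non-numeric"),
    (lambda text: text.replace("20.00,1,1", "20.00,2,1", 1), "flag"),
])
def test_parse_errors_carry_context(tmp_path, mutation, match):
    paths = dict(_table_paths())
    bad = tmp_path / "investigations.csv"
    bad.write_text(mutation(Path(paths["investigations"]).read_text()))
    paths["investigations"] = bad
    with pytest.raises(InventoryParseError, match=match):
        read_inventory_csv(paths)
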