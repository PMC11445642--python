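"""Cost-inventory domain types and unit-cost derivations.

The inventory holds every priced resource item consumed by the clinic:

* diagnostic investigations priced per test,
* drug courses priced per pack with a stated duration,
* staff roles whose time is valued per minute after salary on-costs,
* one-off setup and recurring delivery (program) items.

Salary loading follows the Irish HTA costing convention: employer
social-insurance and pension contributions load the base salary, and
institutional overheads then load the full pay cost.  Per-minute rates
divide the loaded annual cost by contracted minutes per year
(weekly hours x 60 x weeks per year; a 39-hour week and 52 weeks are the
defaults).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .money import MoneyEUR, ValidationError

__all__ = [
    "CASE_TYPES",
    "StaffRole",
    "InvestigationItem",
    "DrugCourse",
    "ContactEvent",
    "ProgramItem",
    "Inventory",
    "loaded_annual_cost",
    "per_minute_cost",
    "contact_cost",
    "drug_course_cost",
    "read_inventory_csv",
    "write_inventory_csv",
]

CASE_TYPES = ("typical", "complex")
PACK_POLICIES = ("prorata", "ceil_whole_pack", "printed_override")
PHASES = ("setup", "ongoing")
CONTACT_CATEGORIES = ("consultation", "admin_coordination")

_CENT = Decimal("0.01")


# ---------------------------------------------------------------------------
# unit-cost derivations
# ---------------------------------------------------------------------------

def _check_rate(name: str, rate: float) -> Decimal:
    d = Decimal(repr(rate)) if isinstance(rate, float) else Decimal(rate)
    if not (0 <= d <= 1):
        raise ValidationError(f"{name} must lie in [0, 1], got {rate}")
    return d


def loaded_annual_cost(base_salary, prsi_rate, pension_rate, overhead_rate) -> Decimal:
    """Annual staff cost after on-costs, in EUR/year.

    base x (1 + PRSI + pension) x (1 + overheads): employer pay-related
    social insurance and pension load the salary, overheads load the
    resulting pay cost.
    """
    base = Decimal(repr(base_salary)) if isinstance(base_salary, float) else Decimal(base_salary)
    if base <= 0:
        raise ValidationError(f"base_salary must be positive, got {base_salary}")
    prsi = _check_rate("prsi_rate", prsi_rate)
    pension = _check_rate("pension_rate", pension_rate)
    overhead = _check_rate("overhead_rate", overhead_rate)
    return base * (1 + prsi + pension) * (1 + overhead)


def per_minute_cost(loaded_annual, weekly_hours=39, weeks_per_year=52) -> Decimal:
    """EUR per contracted working minute, quantized to the cent."""
    annual = Decimal(repr(loaded_annual)) if isinstance(loaded_annual, float) else Decimal(loaded_annual)
    hours = Decimal(repr(weekly_hours)) if isinstance(weekly_hours, float) else Decimal(weekly_hours)
    weeks = Decimal(repr(weeks_per_year)) if isinstance(weeks_per_year, float) else Decimal(weeks_per_year)
    if hours <= 0:
        raise ValidationError(f"weekly_hours must be positive, got {weekly_hours}")
    if weeks <= 0:
        raise ValidationError(f"weeks_per_year must be positive, got {weeks_per_year}")
    minutes = hours * 60 * weeks
    return (annual / minutes).quantize(_CENT, rounding=ROUND_HALF_UP)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaffRole:
    """A staff grade valued per minute of contracted time.

    ``rate_per_minute`` may be pinned directly (when only the per-minute
    rate is published) or derived from ``base_annual_salary`` via
    :func:`loaded_annual_cost` and :func:`per_minute_cost`.
    """

    name: str
    rate_per_minute: Decimal  # EUR/min, cent precision
    base_annual_salary: Optional[Decimal] = None
    prsi_rate: Decimal = Decimal("0.1105")
    pension_rate: Decimal = Decimal("0.04")
    overhead_rate: Decimal = Decimal("0.25")
    weekly_hours: Decimal = Decimal(39)

    def __post_init__(self):
        if self.rate_per_minute <= 0:
            raise ValidationError(f"per_minute_cost for {self.name!r} must be positive")

    @classmethod
    def from_salary(cls, name, base_annual_salary, *, prsi_rate=0.1105,
                    pension_rate=0.04, overhead_rate=0.25, weekly_hours=39,
                    weeks_per_year=52) -> "StaffRole":
        loaded = loaded_annual_cost(base_annual_salary, prsi_rate, pension_rate, overhead_rate)
        rate = per_minute_cost(loaded, weekly_hours, weeks_per_year)
        return cls(name=name, rate_per_minute=rate,
                   base_annual_salary=Decimal(str(base_annual_salary)),
                   prsi_rate=Decimal(str(prsi_rate)), pension_rate=Decimal(str(pension_rate)),
                   overhead_rate=Decimal(str(overhead_rate)), weekly_hours=Decimal(str(weekly_hours)))


@dataclass(frozen=True)
class InvestigationItem:
    """A diagnostic test priced per test."""

    name: str
    unit_cost: MoneyEUR
    applies_to: frozenset = frozenset(CASE_TYPES)

    def __post_init__(self):
        if self.unit_cost.cents <= 0:
            raise ValidationError(f"unit_cost for investigation {self.name!r} must be positive")
        if not self.applies_to:
            raise ValidationError(f"investigation {self.name!r} applies to no case type")
        unknown = set(self.applies_to) - set(CASE_TYPES)
        if unknown:
            raise ValidationError(f"investigation {self.name!r}: unknown case type {sorted(unknown)}")


@dataclass(frozen=True)
class DrugCourse:
    """A drug treatment course priced from pack price and duration.

    ``pack_policy`` chooses the costing rule:

    * ``prorata`` — pack price scaled by (days of treatment / days one
      pack covers), fractional packs allowed;
    * ``ceil_whole_pack`` — whole packs only, rounded up;
    * ``printed_override`` — a canonical published course cost used
      verbatim (for items whose published figure follows a pack-count
      convention the price/duration inputs cannot reproduce).
    """

    name: str
    dose_label: str
    duration_weeks: int
    pack_price: MoneyEUR
    pack_cover_days: int
    pack_policy: str = "prorata"
    printed_cost: Optional[MoneyEUR] = None
    applies_to: frozenset = frozenset(CASE_TYPES)

    def __post_init__(self):
        if self.duration_weeks <= 0:
            raise ValidationError(f"duration_weeks for {self.name!r} must be positive")
        if self.pack_cover_days <= 0:
            raise ValidationError(f"pack_cover_days for {self.name!r} must be positive")
        if self.pack_policy not in PACK_POLICIES:
            raise ValidationError(f"pack_policy {self.pack_policy!r} for {self.name!r} "
                                  f"not one of {PACK_POLICIES}")
        if self.pack_policy == "printed_override" and self.printed_cost is None:
            raise ValidationError(f"{self.name!r}: printed_override requires printed_cost")
        if not self.applies_to or set(self.applies_to) - set(CASE_TYPES):
            raise ValidationError(f"treatment {self.name!r}: invalid applies_to {set(self.applies_to)}")

    @property
    def duration_days(self) -> int:
        return self.duration_weeks * 7


@dataclass(frozen=True)
class ContactEvent:
    """A staff contact: consultations or admin/care-coordination time."""

    role: StaffRole
    minutes: int
    count: int = 1
    category: str = "consultation"

    def __post_init__(self):
        if self.minutes <= 0:
            raise ValidationError(f"contact minutes must be positive, got {self.minutes}")
        if self.count < 1:
            raise ValidationError(f"contact count must be >= 1, got {self.count}")
        if self.category not in CONTACT_CATEGORIES:
            raise ValidationError(f"unknown contact category {self.category!r}")


@dataclass(frozen=True)
class ProgramItem:
    """A one-off setup item or a recurring delivery item."""

    name: str
    units: int
    unit_cost: MoneyEUR
    phase: str = "setup"
    frequency_per_year: int = 1

    def __post_init__(self):
        if self.units < 1:
            raise ValidationError(f"units for {self.name!r} must be >= 1")
        if self.phase not in PHASES:
            raise ValidationError(f"phase {self.phase!r} for {self.name!r} not one of {PHASES}")
        if self.frequency_per_year < 1:
            raise ValidationError(f"frequency_per_year for {self.name!r} must be >= 1")

    def total(self) -> MoneyEUR:
        freq = self.frequency_per_year if self.phase == "ongoing" else 1
        return self.unit_cost * (self.units * freq)


@dataclass(frozen=True)
class Inventory:
    """The full cost inventory: investigations, treatments, staff, program items."""

    investigations: tuple = ()
    treatments: tuple = ()
    staff: Mapping[str, StaffRole] = field(default_factory=dict)
    program_items: tuple = ()

    def role(self, name: str) -> StaffRole:
        try:
            return self.staff[name]
        except KeyError:
            raise LookupError(f"unknown staff role {name!r}") from None

    def items_for(self, case_type: str):
        """(investigations, treatments) applicable to a case type."""
        inv = tuple(i for i in self.investigations if case_type in i.applies_to)
        trt = tuple(t for t in self.treatments if case_type in t.applies_to)
        return inv, trt


# ---------------------------------------------------------------------------
# costing operations
# ---------------------------------------------------------------------------

def contact_cost(event: ContactEvent) -> MoneyEUR:
    """Cost of a staff contact: count x minutes x per-minute rate."""
    per_contact = Decimal(event.minutes) * event.role.rate_per_minute
    cents = (per_contact * 100).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return MoneyEUR(int(cents)) * event.count


def drug_course_cost(course: DrugCourse) -> MoneyEUR:
    """Cost of a full treatment course under the course's pack policy."""
    if course.pack_policy == "printed_override":
        assert course.printed_cost is not None
        return course.printed_cost
    packs = Fraction(course.duration_days, course.pack_cover_days)
    if course.pack_policy == "ceil_whole_pack":
        whole = -(-packs.numerator // packs.denominator)  # ceil
        return course.pack_price * whole
    return course.pack_price.times(packs)


# ---------------------------------------------------------------------------
# CSV schema (UTF-8, comma-delimited, header required)
# ---------------------------------------------------------------------------

INVESTIGATIONS_COLUMNS = ["name", "unit_cost_eur", "typical", "complex"]
TREATMENTS_COLUMNS = ["name", "dose_label", "duration_weeks", "pack_price_eur",
                      "pack_cover_days", "pack_policy", "printed_cost_eur",
                      "typical", "complex"]
PROGRAM_COLUMNS = ["name", "phase", "units", "unit_cost_eur", "frequency_per_year"]
STAFF_COLUMNS = ["role", "per_minute_cost_eur", "base_annual_salary_eur",
                 "prsi_rate", "pension_rate", "overhead_rate", "weekly_hours"]

TABLE_NAMES = ("investigations", "treatments", "staff", "program")


class InventoryParseError(ValidationError):
    """A CSV row or header failed validation; message carries file+row context."""


def _rows(path: Path, required: Sequence[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise InventoryParseError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def _money(path, lineno, field_name, raw, *, optional=False) -> Optional[MoneyEUR]:
    raw = (raw or "").strip()
    if raw == "":
        if optional:
            return None
        raise InventoryParseError(f"{path}:{lineno}: {field_name} is empty")
    try:
        return MoneyEUR.parse(raw)
    except (ValidationError, ArithmeticError):
        raise InventoryParseError(
            f"{path}:{lineno}: non-numeric {field_name} {raw!r}") from None


def _int(path, lineno, field_name, raw) -> int:
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise InventoryParseError(
            f"{path}:{lineno}: non-integer {field_name} {raw!r}") from None


def _applies(path, lineno, row) -> frozenset:
    flags = set()
    for ct in CASE_TYPES:
        val = (row.get(ct) or "").strip()
        if val not in ("0", "1"):
            raise InventoryParseError(
                f"{path}:{lineno}: {ct} flag must be 0 or 1, got {val!r}")
        if val == "1":
            flags.add(ct)
    return frozenset(flags)


def read_inventory_csv(paths: Mapping[str, Path]) -> Inventory:
    """Read the four inventory tables into a validated :class:`Inventory`.

    ``paths`` maps table names (``investigations``, ``treatments``,
    ``staff``, ``program``) to CSV file paths.  Raises
    :class:`InventoryParseError` with file and row context on any schema
    violation.
    """
    unknown = set(paths) - set(TABLE_NAMES)
    if unknown:
        raise InventoryParseError(f"unknown inventory table(s) {sorted(unknown)}")

    investigations = []
    for p, lineno, row in ((paths["investigations"], ln, r)
                           for ln, r in _rows(Path(paths["investigations"]), INVESTIGATIONS_COLUMNS)):
        try:
            investigations.append(InvestigationItem(
                name=row["name"],
                unit_cost=_money(p, lineno, "unit_cost_eur", row["unit_cost_eur"]),
                applies_to=_applies(p, lineno, row)))
        except ValidationError as exc:
            raise InventoryParseError(f"{p}:{lineno}: {exc}") from None

    treatments = []
    for ln, row in _rows(Path(paths["treatments"]), TREATMENTS_COLUMNS):
        p = paths["treatments"]
        try:
            treatments.append(DrugCourse(
                name=row["name"], dose_label=row["dose_label"],
                duration_weeks=_int(p, ln, "duration_weeks", row["duration_weeks"]),
                pack_price=_money(p, ln, "pack_price_eur", row["pack_price_eur"]),
                pack_cover_days=_int(p, ln, "pack_cover_days", row["pack_cover_days"]),
                pack_policy=(row["pack_policy"] or "prorata").strip(),
                printed_cost=_money(p, ln, "printed_cost_eur", row.get("printed_cost_eur"), optional=True),
                applies_to=_applies(p, ln, row)))
        except ValidationError as exc:
            raise InventoryParseError(f"{p}:{ln}: {exc}") from None

    staff = {}
    for ln, row in _rows(Path(paths["staff"]), STAFF_COLUMNS):
        p = paths["staff"]
        try:
            rate = _money(p, ln, "per_minute_cost_eur", row["per_minute_cost_eur"])
            base = (row.get("base_annual_salary_eur") or "").strip()
            staff[row["role"]] = StaffRole(
                name=row["role"], rate_per_minute=rate.euros,
                base_annual_salary=Decimal(base) if base else None,
                prsi_rate=Decimal(row["prsi_rate"]), pension_rate=Decimal(row["pension_rate"]),
                overhead_rate=Decimal(row["overhead_rate"]), weekly_hours=Decimal(row["weekly_hours"]))
        except (ValidationError, ArithmeticError) as exc:
            raise InventoryParseError(f"{p}:{ln}: {exc}") from None

    program = []
    for ln, row in _rows(Path(paths["program"]), PROGRAM_COLUMNS):
        p = paths["program"]
        try:
            program.append(ProgramItem(
                name=row["name"], phase=(row["phase"] or "").strip(),
                units=_int(p, ln, "units", row["units"]),
                unit_cost=_money(p, ln, "unit_cost_eur", row["unit_cost_eur"]),
                frequency_per_year=_int(p, ln, "frequency_per_year", row["frequency_per_year"])))
        except ValidationError as exc:
            raise InventoryParseError(f"{p}:{ln}: {exc}") from None

    return Inventory(investigations=tuple(investigations), treatments=tuple(treatments),
                     staff=staff, program_items=tuple(program))


def write_inventory_csv(inventory: Inventory, paths: Mapping[str, Path]) -> None:
    """Write an inventory back to the four-table CSV schema (lossless round-trip)."""

    def _fmt(m: Optional[MoneyEUR]) -> str:
        return "" if m is None else f"{m.euros:.2f}"

    with open(paths["investigations"], "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, INVESTIGATIONS_COLUMNS)
        w.writeheader()
        for item in inventory.investigations:
            w.writerow({"name": item.name, "unit_cost_eur": _fmt(item.unit_cost),
                        "typical": int("typical" in item.applies_to),
                        "complex": int("complex" in item.applies_to)})

    with open(paths["treatments"], "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, TREATMENTS_COLUMNS)
        w.writeheader()
        for t in inventory.treatments:
            w.writerow({"name": t.name, "dose_label": t.dose_label,
                        "duration_weeks": t.duration_weeks,
                        "pack_price_eur": _fmt(t.pack_price),
                        "pack_cover_days": t.pack_cover_days,
                        "pack_policy": t.pack_policy,
                        "printed_cost_eur": _fmt(t.printed_cost),
                        "typical": int("typical" in t.applies_to),
                        "complex": int("complex" in t.applies_to)})

    with open(paths["staff"], "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, STAFF_COLUMNS)
        w.writeheader()
        for role in inventory.staff.values():
            w.writerow({"role": role.name,
                        "per_minute_cost_eur": f"{role.rate_per_minute:.2f}",
                        "base_annual_salary_eur": "" if role.base_annual_salary is None
                                                  else f"{role.base_annual_salary}",
                        "prsi_rate": f"{role.prsi_rate}", "pension_rate": f"{role.pension_rate}",
                        "overhead_rate": f"{role.overhead_rate}", "weekly_hours": f"{role.weekly_hours}"})

    with open(paths["program"], "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, PROGRAM_COLUMNS)
        w.writeheader()
        for item in inventory.program_items:
            w.writerow({"name": item.name, "phase": item.phase, "units": item.units,
                        "unit_cost_eur": _fmt(item.unit_cost),
                        "frequency_per_year": item.frequency_per_year})
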