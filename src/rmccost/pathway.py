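"""Care-pathway scenarios and per-patient cost breakdowns.

A :class:`Scenario` itemises the pathway for one case archetype (typical or
complex): the investigations performed, the drug courses prescribed, the
consultation and admin/care-coordination contacts, and the two outcome
arms (a subsequent pregnancy, costed as reassurance ultrasound scans, or
no further pregnancy).  Per-patient costs are cent-precision sums over the
itemised pathway; whole-euro figures are presentation views only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import yaml

from .inventory import (ContactEvent, DrugCourse, Inventory, InvestigationItem,
                        contact_cost, drug_course_cost)
from .money import MoneyEUR, ValidationError, msum

__all__ = [
    "OUTCOMES", "CATEGORIES",
    "OutcomeArm", "Scenario", "PerPatientCost", "LedgerRow",
    "category_subtotal", "outcome_cost", "per_patient_cost",
    "itemized_ledger", "build_scenario", "load_scenarios",
]

OUTCOMES = ("pregnant", "not_pregnant")
CATEGORIES = ("investigations", "treatment", "hcp_time", "admin_time", "outcome")


@dataclass(frozen=True)
class OutcomeArm:
    """Outcome-dependent follow-on care: reassurance scans in a subsequent pregnancy."""

    outcome: str
    n_scans: int = 0
    scan_price: MoneyEUR = MoneyEUR(12500)

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.n_scans < 0:
            raise ValidationError("n_scans must be >= 0")
        if self.outcome == "not_pregnant" and self.n_scans != 0:
            raise ValidationError("not_pregnant arm cannot include reassurance scans")


@dataclass(frozen=True)
class Scenario:
    """An itemised care pathway for one case archetype."""

    case_type: str
    investigations: Tuple[InvestigationItem, ...] = ()
    treatments: Tuple[DrugCourse, ...] = ()
    consultations: Tuple[ContactEvent, ...] = ()
    admin: Tuple[ContactEvent, ...] = ()
    outcome_arms: Mapping[str, OutcomeArm] = field(default_factory=dict)

    def __post_init__(self):
        for item in (*self.investigations, *self.treatments):
            if self.case_type not in item.applies_to:
                raise ValidationError(
                    f"{item.name!r} does not apply to case type {self.case_type!r}")
        for ev in self.consultations:
            if ev.category != "consultation":
                raise ValidationError("consultations must have category 'consultation'")
        for ev in self.admin:
            if ev.category != "admin_coordination":
                raise ValidationError("admin events must have category 'admin_coordination'")
        for outcome in OUTCOMES:
            if outcome not in self.outcome_arms:
                raise ValidationError(f"scenario missing outcome arm {outcome!r}")

    def arm(self, outcome: str) -> OutcomeArm:
        if outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {outcome!r}")
        return self.outcome_arms[outcome]


@dataclass(frozen=True)
class LedgerRow:
    item: str
    category: str
    amount: MoneyEUR


@dataclass(frozen=True)
class PerPatientCost:
    """Per-patient cost breakdown by category, at cent precision."""

    case_type: str
    outcome: str
    subtotals: Mapping[str, MoneyEUR]
    total: MoneyEUR

    @property
    def presentation(self) -> Dict[str, int]:
        """Whole-euro view of each subtotal and the total (round-half-up)."""
        view = {cat: amt.present_euros() for cat, amt in self.subtotals.items()}
        view["total"] = self.total.present_euros()
        return view


def outcome_cost(arm: OutcomeArm) -> MoneyEUR:
    """Cost of an outcome arm: number of scans x scan price."""
    return arm.scan_price * arm.n_scans


def category_subtotal(scenario: Scenario, category: str, outcome: str = "pregnant") -> MoneyEUR:
    """Cent-precision subtotal of one cost category.

    The ``outcome`` argument matters only for the ``outcome`` category
    (scan costs differ between arms); all other categories are
    outcome-invariant.
    """
    if category == "investigations":
        return msum(i.unit_cost for i in scenario.investigations)
    if category == "treatment":
        return msum(drug_course_cost(t) for t in scenario.treatments)
    if category == "hcp_time":
        return msum(contact_cost(e) for e in scenario.consultations)
    if category == "admin_time":
        return msum(contact_cost(e) for e in scenario.admin)
    if category == "outcome":
        return outcome_cost(scenario.arm(outcome))
    raise ValidationError(f"unknown category {category!r}")


def per_patient_cost(scenario: Scenario, outcome: str) -> PerPatientCost:
    """Full per-patient breakdown; total is the exact sum of the five subtotals."""
    if outcome not in OUTCOMES:
        raise ValidationError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    subtotals = {cat: category_subtotal(scenario, cat, outcome) for cat in CATEGORIES}
    total = msum(subtotals.values())
    return PerPatientCost(case_type=scenario.case_type, outcome=outcome,
                          subtotals=subtotals, total=total)


def itemized_ledger(scenario: Scenario, outcome: str) -> List[LedgerRow]:
    """One row per costed event — the brute-force audit trail.

    The ledger enumerates every investigation, drug course, staff contact
    and scan individually; its sum equals the aggregated per-patient total
    at cent precision (this identity is the engine's main self-check).
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    rows: List[LedgerRow] = []
    for item in scenario.investigations:
        rows.append(LedgerRow(item.name, "investigations", item.unit_cost))
    for course in scenario.treatments:
        rows.append(LedgerRow(course.name, "treatment", drug_course_cost(course)))
    for ev in scenario.consultations:
        for _ in range(ev.count):
            rows.append(LedgerRow(ev.role.name, "hcp_time",
                                  contact_cost(ContactEvent(ev.role, ev.minutes, 1, ev.category))))
    for ev in scenario.admin:
        for _ in range(ev.count):
            rows.append(LedgerRow(ev.role.name, "admin_time",
                                  contact_cost(ContactEvent(ev.role, ev.minutes, 1, ev.category))))
    arm = scenario.arm(outcome)
    for i in range(arm.n_scans):
        rows.append(LedgerRow(f"reassurance_scan_{i + 1}", "outcome", arm.scan_price))
    return rows


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

def build_scenario(inventory: Inventory, case_type: str, *,
                   consultations, admin, outcome_arms) -> Scenario:
    """Assemble a scenario from an inventory plus contact/outcome definitions.

    Investigations and treatments are selected from the inventory by their
    declared case-type applicability.  ``consultations`` and ``admin`` are
    iterables of (role name, minutes, count) triples.
    """
    inv_items, trt_items = inventory.items_for(case_type)
    cons = tuple(ContactEvent(inventory.role(r), m, c, "consultation")
                 for r, m, c in consultations)
    adm = tuple(ContactEvent(inventory.role(r), m, c, "admin_coordination")
                for r, m, c in admin)
    return Scenario(case_type=case_type, investigations=inv_items, treatments=trt_items,
                    consultations=cons, admin=adm, outcome_arms=dict(outcome_arms))


def load_scenarios(path, inventory: Inventory) -> Dict[str, Scenario]:
    """Load scenario definitions from a YAML config file.

    Expected layout::

        scenarios:
          typical:
            consultations: [{role: obstetrician, minutes: 30, count: 1}, ...]
            admin:         [{role: obstetrician, minutes: 30, count: 1}, ...]
            outcomes:
              pregnant:     {n_scans: 2, scan_price_eur: 125.00}
              not_pregnant: {n_scans: 0}
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scenarios" not in cfg:
        raise ValidationError(f"{path}: missing top-level 'scenarios' key")
    scenarios = {}
    for case_type, block in cfg["scenarios"].items():
        arms = {}
        for outcome, arm_cfg in (block.get("outcomes") or {}).items():
            arms[outcome] = OutcomeArm(
                outcome=outcome, n_scans=int(arm_cfg.get("n_scans", 0)),
                scan_price=MoneyEUR.parse(str(arm_cfg.get("scan_price_eur", "125.00"))))
        scenarios[case_type] = build_scenario(
            inventory, case_type,
            consultations=[(c["role"], int(c["minutes"]), int(c.get("count", 1)))
                           for c in block.get("consultations", [])],
            admin=[(c["role"], int(c["minutes"]), int(c.get("count", 1)))
                   for c in block.get("admin", [])],
            outcome_arms=arms)
    return scenarios
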