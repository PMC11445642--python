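"""Pinned study fixture and randomized model generator.

Two entry points:

* :func:`paper_fixture` returns the packaged transcription of the study's
  cost inventory, care-pathway scenarios, program items and population
  inputs — the reference dataset every headline figure is computed from.
* :func:`random_model` draws a structurally identical model at random
  (uniformly within configured ranges), for property-testing every stage
  of the engine on inputs it has never seen.  Identical seed and config
  give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from importlib import resources
from typing import Dict, NamedTuple, Tuple

import numpy as np

from .budget import PopulationModel, CostModel
from .inventory import (ContactEvent, DrugCourse, Inventory, InvestigationItem,
                        ProgramItem, StaffRole, read_inventory_csv)
from .money import MoneyEUR, ValidationError
from .pathway import OutcomeArm, Scenario, load_scenarios, per_patient_cost

__all__ = ["ModelBundle", "GeneratorConfig", "paper_fixture", "random_model",
           "fixture_paths", "subgroup_costs", "cost_model"]


class ModelBundle(NamedTuple):
    """A complete costing model: inventory, scenarios, population, program items."""

    inventory: Inventory
    scenarios: Dict[str, Scenario]
    population: PopulationModel
    program_items: Tuple[ProgramItem, ...]


def subgroup_costs(scenarios: Dict[str, Scenario]) -> Dict[str, MoneyEUR]:
    """Per-patient totals keyed by subgroup (case type x outcome)."""
    out = {}
    for case_type, scenario in scenarios.items():
        for outcome in ("pregnant", "not_pregnant"):
            out[f"{case_type}_{outcome}"] = per_patient_cost(scenario, outcome).total
    return out


def cost_model(bundle: ModelBundle) -> CostModel:
    """Collapse a bundle to the system-level :class:`~rmccost.budget.CostModel`."""
    return CostModel(program_items=tuple(bundle.program_items),
                     population=bundle.population,
                     per_patient=subgroup_costs(bundle.scenarios))


# ---------------------------------------------------------------------------
# pinned fixture
# ---------------------------------------------------------------------------

def fixture_paths() -> Dict[str, str]:
    """Paths of the packaged fixture files (CSV inventory + YAML configs)."""
    base = resources.files("rmccost").joinpath("data")
    return {name: str(base.joinpath(fname)) for name, fname in (
        ("investigations", "investigations.csv"),
        ("treatments", "treatments.csv"),
        ("staff", "staff.csv"),
        ("program", "program.csv"),
        ("scenarios", "scenarios.yaml"),
        ("population", "population.yaml"),
    )}


def paper_fixture() -> ModelBundle:
    """The packaged reference dataset, transcribed from the published cost tables.

    Immutable in the sense that repeated calls return structurally equal
    bundles built from the same packaged files.
    """
    from .budget import load_population

    paths = fixture_paths()
    inventory = read_inventory_csv({k: paths[k] for k in
                                    ("investigations", "treatments", "staff", "program")})
    scenarios = load_scenarios(paths["scenarios"], inventory)
    population = load_population(paths["population"])
    return ModelBundle(inventory=inventory, scenarios=scenarios,
                       population=population, program_items=inventory.program_items)


# ---------------------------------------------------------------------------
# randomized generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges for the random model generator.

    All ranges are inclusive; money ranges are in euro.  Defaults are sized
    like the reference inventory (a dozen investigations, a handful of
    drug courses, two staff roles, outpatient-scale prices).
    """

    seed: int = 0
    n_investigations: Tuple[int, int] = (5, 15)
    n_treatments: Tuple[int, int] = (2, 7)
    investigation_price: Tuple[float, float] = (5.0, 300.0)
    pack_price: Tuple[float, float] = (2.0, 120.0)
    pack_cover_days: Tuple[int, int] = (7, 30)
    duration_weeks: Tuple[int, int] = (4, 40)
    salary: Tuple[float, float] = (40_000.0, 180_000.0)
    contact_minutes: Tuple[int, ...] = (15, 30, 45, 60)
    scan_price: Tuple[float, float] = (80.0, 200.0)
    n_scans_pregnant: Tuple[int, int] = (1, 4)
    program_item_cost: Tuple[float, float] = (40.0, 12_000.0)
    population: Tuple[int, int] = (100_000, 2_000_000)
    prevalence: Tuple[float, float] = (0.01, 0.08)
    complex_share: Tuple[float, float] = (0.05, 0.30)
    pregnancy_prob: Tuple[float, float] = (0.4, 0.9)

    def __post_init__(self):
        for name in ("n_investigations", "n_treatments", "investigation_price",
                     "pack_price", "pack_cover_days", "duration_weeks", "salary",
                     "scan_price", "n_scans_pregnant", "program_item_cost",
                     "population", "prevalence", "complex_share", "pregnancy_prob"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: infeasible range ({lo} > {hi})")
            if lo < 0:
                raise ValidationError(f"{name}: range must be non-negative")
        if not self.contact_minutes:
            raise ValidationError("contact_minutes choice set is empty")


def _money_in(rng: np.random.Generator, lo: float, hi: float) -> MoneyEUR:
    cents = int(rng.integers(round(lo * 100), round(hi * 100) + 1))
    return MoneyEUR(max(cents, 1))


def _applies(rng: np.random.Generator) -> frozenset:
    choice = rng.integers(0, 3)
    return (frozenset({"typical"}), frozenset({"complex"}),
            frozenset({"typical", "complex"}))[int(choice)]


def random_model(config: GeneratorConfig) -> ModelBundle:
    """Draw a structurally valid random costing model.

    Every generated object passes the same validation as parsed inputs, so
    any property that holds here holds for arbitrary well-formed
    inventories.
    """
    rng = np.random.default_rng(config.seed)

    investigations = tuple(
        InvestigationItem(name=f"inv_{i:02d}",
                          unit_cost=_money_in(rng, *config.investigation_price),
                          applies_to=_applies(rng))
        for i in range(int(rng.integers(*config.n_investigations, endpoint=True))))

    policies = ("prorata", "ceil_whole_pack", "printed_override")
    treatments = []
    for i in range(int(rng.integers(*config.n_treatments, endpoint=True))):
        policy = policies[int(rng.integers(0, len(policies)))]
        printed = _money_in(rng, *config.pack_price) if policy == "printed_override" else None
        treatments.append(DrugCourse(
            name=f"drug_{i:02d}", dose_label=f"{int(rng.integers(1, 500))}mg",
            duration_weeks=int(rng.integers(*config.duration_weeks, endpoint=True)),
            pack_price=_money_in(rng, *config.pack_price),
            pack_cover_days=int(rng.integers(*config.pack_cover_days, endpoint=True)),
            pack_policy=policy, printed_cost=printed, applies_to=_applies(rng)))

    staff = {}
    for role_name in ("clinician", "specialist_midwife"):
        salary = float(rng.uniform(*config.salary))
        staff[role_name] = StaffRole.from_salary(role_name, round(salary, 2))
    inventory_staff = staff

    def _contacts(category: str):
        events = []
        for role_name in inventory_staff:
            minutes = int(rng.choice(config.contact_minutes))
            count = int(rng.integers(1, 4))
            events.append(ContactEvent(inventory_staff[role_name], minutes, count, category))
        return tuple(events)

    program_items = []
    for i in range(int(rng.integers(2, 6))):
        program_items.append(ProgramItem(
            name=f"setup_{i:02d}", units=int(rng.integers(1, 4)),
            unit_cost=_money_in(rng, *config.program_item_cost), phase="setup"))
    for i in range(int(rng.integers(1, 4))):
        program_items.append(ProgramItem(
            name=f"ongoing_{i:02d}", units=int(rng.integers(1, 3)),
            unit_cost=_money_in(rng, *config.program_item_cost), phase="ongoing",
            frequency_per_year=int(rng.integers(1, 53))))
    program_items = tuple(program_items)

    inventory = Inventory(investigations=investigations, treatments=tuple(treatments),
                          staff=inventory_staff, program_items=program_items)

    scan_price = _money_in(rng, *config.scan_price)
    scenarios = {}
    for case_type in ("typical", "complex"):
        inv_items, trt_items = inventory.items_for(case_type)
        n_scans = int(rng.integers(*config.n_scans_pregnant, endpoint=True))
        scenarios[case_type] = Scenario(
            case_type=case_type, investigations=inv_items, treatments=trt_items,
            consultations=_contacts("consultation"), admin=_contacts("admin_coordination"),
            outcome_arms={
                "pregnant": OutcomeArm("pregnant", n_scans, scan_price),
                "not_pregnant": OutcomeArm("not_pregnant", 0, scan_price)})

    population = PopulationModel(
        reproductive_population=int(rng.integers(*config.population, endpoint=True)),
        rm_prevalence=Decimal(repr(round(float(rng.uniform(*config.prevalence)), 4))),
        complex_share=Decimal(repr(round(float(rng.uniform(*config.complex_share)), 4))),
        pregnancy_prob=Decimal(repr(round(float(rng.uniform(*config.pregnancy_prob)), 4))))

    return ModelBundle(inventory=inventory, scenarios=scenarios,
                       population=population, program_items=program_items)
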