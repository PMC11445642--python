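"""Program costs and prevalence-based budget-impact extrapolation.

Setup and ongoing delivery costs are simple item sums.  The budget impact
extrapolates per-patient pathway costs to the eligible population: women
of reproductive age x prevalence of two or more consecutive losses, split
into a typical/complex case mix and, within each case type, into those who
progress to another pregnancy and those who do not.

Subgroup counts are derived with round-half-up on the pregnant arm and the
complement taken by subtraction, so counts are conserved exactly at every
split.  Published headline counts may be pinned via ``subgroup_overrides``
when an external table's printed figures must be reproduced verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Dict, Iterable, Mapping, Optional

import yaml

from .inventory import ProgramItem
from .money import MoneyEUR, ValidationError, msum, round_half_up_int

__all__ = [
    "SUBGROUPS", "PopulationModel", "BudgetResult", "CostModel",
    "program_total", "subgroup_populations", "budget_impact", "load_population",
]

SUBGROUPS = ("typical_pregnant", "typical_not_pregnant",
             "complex_pregnant", "complex_not_pregnant")


def _check_fraction(name: str, value) -> Decimal:
    d = Decimal(repr(value)) if isinstance(value, float) else Decimal(value)
    if not (0 <= d <= 1):
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return d


@dataclass(frozen=True)
class PopulationModel:
    """Population inputs for the budget-impact extrapolation.

    Defaults are the study conditions: 1,203,000 women of reproductive age,
    5% prevalence of two or more consecutive first-trimester losses, a 10%
    complex-case share and a 70% probability of progressing to another
    pregnancy.
    """

    reproductive_population: int = 1_203_000
    rm_prevalence: Decimal = Decimal("0.05")
    complex_share: Decimal = Decimal("0.10")
    pregnancy_prob: Decimal = Decimal("0.70")
    subgroup_overrides: Optional[Mapping[str, int]] = None

    def __post_init__(self):
        if self.reproductive_population < 0:
            raise ValidationError("reproductive_population must be non-negative")
        object.__setattr__(self, "rm_prevalence", _check_fraction("rm_prevalence", self.rm_prevalence))
        object.__setattr__(self, "complex_share", _check_fraction("complex_share", self.complex_share))
        object.__setattr__(self, "pregnancy_prob", _check_fraction("pregnancy_prob", self.pregnancy_prob))
        if self.subgroup_overrides is not None:
            unknown = set(self.subgroup_overrides) - set(SUBGROUPS)
            if unknown:
                raise ValidationError(f"unknown subgroup override(s) {sorted(unknown)}")

    @property
    def rm_population(self) -> int:
        """Eligible population: reproductive-age count x prevalence."""
        return round_half_up_int(Decimal(self.reproductive_population) * self.rm_prevalence)


def subgroup_populations(model: PopulationModel, *, use_overrides: bool = True) -> Dict[str, int]:
    """Subgroup head counts for the four case-type x outcome cells.

    Derivation conserves counts exactly: the typical share is rounded
    half-up and complex is the remainder; within each case type the
    pregnant arm is rounded half-up and the not-pregnant arm is the
    remainder.  When the model carries ``subgroup_overrides`` (pinned
    published counts) and ``use_overrides`` is true, those replace the
    derived values verbatim.
    """
    rm = model.rm_population
    typical = round_half_up_int(Decimal(rm) * (1 - model.complex_share))
    complex_ = rm - typical
    counts = {}
    for case_type, n_case in (("typical", typical), ("complex", complex_)):
        pregnant = round_half_up_int(Decimal(n_case) * model.pregnancy_prob)
        counts[f"{case_type}_pregnant"] = pregnant
        counts[f"{case_type}_not_pregnant"] = n_case - pregnant
    if use_overrides and model.subgroup_overrides:
        counts.update(model.subgroup_overrides)
    return counts


def program_total(items: Iterable[ProgramItem], phase: str) -> MoneyEUR:
    """Total program cost for one phase (``setup`` or ``ongoing``)."""
    if phase not in ("setup", "ongoing"):
        raise ValidationError(f"phase must be 'setup' or 'ongoing', got {phase!r}")
    return msum(item.total() for item in items if item.phase == phase)


@dataclass(frozen=True)
class BudgetResult:
    """The budget-impact table: counts, per-patient costs, subgroup and grand totals.

    Program costs are reported alongside the patient-care total, not
    folded into it.
    """

    subgroup_counts: Mapping[str, int]
    per_patient: Mapping[str, MoneyEUR]
    subgroup_totals: Mapping[str, MoneyEUR]
    grand_total: MoneyEUR
    rm_population: int
    average_per_patient: Decimal  # EUR, unrounded
    program_setup: MoneyEUR = MoneyEUR(0)
    program_ongoing_annual: MoneyEUR = MoneyEUR(0)

    @property
    def average_per_patient_presented(self) -> int:
        return round_half_up_int(self.average_per_patient)


def budget_impact(model: PopulationModel, per_patient: Mapping[str, MoneyEUR],
                  program_items: Iterable[ProgramItem] = ()) -> BudgetResult:
    """Extrapolate per-patient costs to the eligible population.

    The average per patient divides the grand total by the eligible
    population count (the prevalence-derived total, not the sum of any
    overridden subgroup counts).
    """
    missing = [s for s in SUBGROUPS if s not in per_patient]
    if missing:
        raise ValidationError(f"per_patient costs missing for subgroup(s) {missing}")
    counts = subgroup_populations(model)
    subgroup_totals = {s: per_patient[s] * counts[s] for s in SUBGROUPS}
    grand_total = msum(subgroup_totals.values())
    rm = model.rm_population
    average = grand_total.euros / rm if rm else Decimal(0)
    program_items = tuple(program_items)
    return BudgetResult(
        subgroup_counts=counts, per_patient=dict(per_patient),
        subgroup_totals=subgroup_totals, grand_total=grand_total,
        rm_population=rm, average_per_patient=average,
        program_setup=program_total(program_items, "setup"),
        program_ongoing_annual=program_total(program_items, "ongoing"))


@dataclass(frozen=True)
class CostModel:
    """Everything the system-level analyses need: program items, population,
    per-patient costs per subgroup (at cent precision)."""

    program_items: tuple
    population: PopulationModel
    per_patient: Mapping[str, MoneyEUR]

    def result(self) -> BudgetResult:
        return budget_impact(self.population, self.per_patient, self.program_items)


def load_population(path) -> PopulationModel:
    """Load a population config from YAML.

    Keys: ``reproductive_population``, ``rm_prevalence``, ``complex_share``,
    ``pregnancy_prob`` and optional ``subgroup_overrides``.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("reproductive_population",):
        if key in cfg:
            kwargs[key] = int(cfg[key])
    for key in ("rm_prevalence", "complex_share", "pregnancy_prob"):
        if key in cfg:
            kwargs[key] = Decimal(str(cfg[key]))
    if cfg.get("subgroup_overrides"):
        kwargs["subgroup_overrides"] = {k: int(v) for k, v in cfg["subgroup_overrides"].items()}
    return PopulationModel(**kwargs)
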