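"""One-way deterministic sensitivity analysis.

Each named parameter block is perturbed by a fraction delta (default 10%)
in isolation; every other input is held at its base value.  Perturbation
is applied to the *unrounded* cent-precision base (or the integer head
count for population blocks, re-rounded half-up), and whole-euro rounding
is applied only when results are presented.  Cost-driver rankings order
blocks by their swing (high minus low), which is independent of
presentation rounding.

Block grammar::

    setup_costs                      total one-off setup cost
    ongoing_costs                    total annual delivery cost
    per_patient_cost:<subgroup>      one subgroup's per-patient cost
    population:<subgroup>            one subgroup's head count
    setup_item:<name>                a single setup program item
    ongoing_item:<name>              a single ongoing program item

Subgroups are ``typical_pregnant``, ``typical_not_pregnant``,
``complex_pregnant``, ``complex_not_pregnant``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import List, Sequence, Union

from .budget import SUBGROUPS, CostModel, program_total, subgroup_populations
from .money import MoneyEUR, ValidationError, round_half_up_int

__all__ = ["SensitivitySpec", "SensitivityResult", "one_way", "driver_ranking"]


@dataclass(frozen=True)
class SensitivitySpec:
    """A parameter block to perturb and the perturbation fraction."""

    block: str
    delta: Decimal = Decimal("0.10")

    def __post_init__(self):
        d = Decimal(repr(self.delta)) if isinstance(self.delta, float) else Decimal(self.delta)
        object.__setattr__(self, "delta", d)
        if not (0 < d < 1):
            raise ValidationError(f"delta must lie in (0, 1), got {self.delta}")


@dataclass(frozen=True)
class SensitivityResult:
    """Low/base/high values of one block under a ±delta perturbation.

    ``low``/``base``/``high`` are Decimals in euro for cost blocks and
    integers for population blocks; ``swing`` = high − low.
    """

    block: str
    low: Union[Decimal, int]
    base: Union[Decimal, int]
    high: Union[Decimal, int]

    @property
    def swing(self) -> Union[Decimal, int]:
        return self.high - self.low

    def presented(self):
        """(low, base, high) as whole euros / counts, round-half-up."""
        return tuple(v if isinstance(v, int) else round_half_up_int(v)
                     for v in (self.low, self.base, self.high))


def _base_value(model: CostModel, block: str) -> Union[MoneyEUR, int]:
    if block == "setup_costs":
        return program_total(model.program_items, "setup")
    if block == "ongoing_costs":
        return program_total(model.program_items, "ongoing")
    kind, _, arg = block.partition(":")
    if kind == "per_patient_cost":
        if arg not in SUBGROUPS:
            raise ValidationError(f"unknown subgroup {arg!r} in block {block!r}")
        return model.per_patient[arg]
    if kind == "population":
        if arg not in SUBGROUPS:
            raise ValidationError(f"unknown subgroup {arg!r} in block {block!r}")
        return subgroup_populations(model.population)[arg]
    if kind in ("setup_item", "ongoing_item"):
        phase = kind.split("_")[0]
        for item in model.program_items:
            if item.phase == phase and item.name == arg:
                return item.total()
        raise ValidationError(f"no {phase} program item named {arg!r}")
    raise ValidationError(f"unknown sensitivity block {block!r}")


def one_way(model: CostModel, spec: SensitivitySpec) -> SensitivityResult:
    """Perturb one block by ±delta and return low/base/high.

    Cost blocks scale linearly on their cent-precision base; population
    blocks scale the head count and re-round half-up to a whole person.
    """
    base = _base_value(model, spec.block)
    if isinstance(base, int):  # population head count
        low = round_half_up_int(Decimal(base) * (1 - spec.delta))
        high = round_half_up_int(Decimal(base) * (1 + spec.delta))
        return SensitivityResult(spec.block, low, base, high)
    low = base.times(1 - spec.delta)
    high = base.times(1 + spec.delta)
    return SensitivityResult(spec.block, low.euros, base.euros, high.euros)


def driver_ranking(model: CostModel, specs: Sequence[SensitivitySpec]) -> List[SensitivityResult]:
    """Rank blocks by descending swing (the tornado-diagram ordering).

    Ties break lexicographically on the block name so rankings are fully
    deterministic.
    """
    if not specs:
        raise ValidationError("driver_ranking requires at least one spec")
    results = [one_way(model, spec) for spec in specs]
    return sorted(results, key=lambda r: (-Decimal(r.swing), r.block))
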