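# Methods note

## Scope and model

`rmccost` implements a deterministic, desk-scale costing model with four
stages:

1. **Unit-cost derivation** (`rmccost.inventory`) — salary loading,
   per-minute staff rates, per-test investigation prices, pack-priced drug
   courses, one-off setup and recurring delivery items.
2. **Per-patient pathway costing** (`rmccost.pathway`) — two case
   archetypes (typical, complex) × two outcome arms (pregnant,
   not-pregnant), with category subtotals for investigations, treatment,
   clinician time, admin/care-coordination time and outcome-dependent
   reassurance scans.
3. **Budget impact** (`rmccost.budget`) — prevalence-based extrapolation of
   per-patient costs to the eligible population, reported alongside (never
   folded into) program setup and delivery costs.
4. **One-way sensitivity** (`rmccost.sensitivity`) — ±δ perturbation of one
   named block at a time and swing-based cost-driver ranking.

There is no patient-level stochastic simulation, no discounting (all
results are one-year figures), no currency conversion, and no clinical
effectiveness modelling: the model prices a fixed care pathway, it does not
evaluate it.

## Monetary arithmetic

All amounts are integer cents (`MoneyEUR`), so sums are exact. Quantities
born non-integral — pro-rata pack fractions, minutes × per-minute rates —
are quantized half-up to the cent at the item level. Whole-euro figures are
*presentation* views (round-half-up) computed from cent-precision sums,
never sums of pre-rounded items; this single convention reproduces the
reference tables' printed subtotals, including those that require cents to
land correctly (e.g. the complex investigation subtotal €1,306.69 → €1,307).
Presentation never moves a value by more than €0.50 (property-tested).

## Key parameters and defaults

| parameter | default | meaning |
|---|---|---|
| PRSI / pension / overhead rates | 0.1105 / 0.04 / 0.25 | employer on-costs loading base salaries |
| weekly hours, weeks/year | 39, 52 | contracted time behind per-minute rates |
| scan price, scans | €125; 2 typical / 4 complex | outcome-arm follow-on care |
| reproductive population | 1,203,000 | women aged 15–49 |
| prevalence of ≥2 consecutive losses | 5% | eligible fraction |
| complex-case share | 10% | case mix |
| pregnancy probability | 70% | outcome split within each case type |
| sensitivity δ | 0.10 | one-way perturbation fraction |

On-cost composition order is (1 + PRSI + pension) applied to salary, then
× (1 + overheads): overheads conventionally load the full pay cost. With a
39-hour week and 52 weeks, the packaged per-minute rates (€2.98
obstetrician, €0.77 bereavement midwife) imply loaded annual costs of
€362,606.40 and €93,693.60 respectively; the fixture pins the per-minute
rates directly, so the weeks-per-year convention never affects
reconciliation.

## Numerical choices

- **Pack policies.** Treatment durations are stated in weeks and converted
  at 7 days/week. Pro-rata is the default. Three courses in the packaged
  dataset (folate €65.11, progesterone 100 mg €39.00, progesterone 400 mg
  €136.00) carry `printed_override`: their published course costs follow a
  pack-count convention the price/duration inputs cannot reproduce under
  any single rounding rule (e.g. folate's €65.11 implies 8.5 packs where 36
  weeks pro-rata gives 8.4), so the published figure is pinned and the
  discrepancy documented here rather than forced through arithmetic.
- **Subgroup counts.** Derivation rounds the pregnant arm half-up and takes
  the complement by subtraction, so counts are conserved exactly at every
  split — independent rounding would not be (the reference table's own
  printed counts sum to 54,136 typical against a 54,135 header, and its
  complex-pregnant 4,221 differs from the conserving derivation's 4,211).
  The packaged population config therefore pins the published counts as
  `subgroup_overrides`; `subgroup_populations(..., use_overrides=False)`
  exposes the self-consistent derivation.
- **Average per patient** divides the grand total by the prevalence-derived
  eligible population (60,150), not by the sum of overridden subgroup
  counts (60,161).
- **Sensitivity bases.** Perturbation applies to the unrounded
  cent-precision base, then presentation rounding: €1,634.19 × 1.1 →
  €1,797.61 → €1,798, which matches the published band where perturbing the
  rounded €1,634 would not. Population counts are re-rounded half-up to
  whole people. Rankings use the swing (high − low) and tie-break on the
  block name, so they are independent of presentation rounding.
- **Known ±€1 residuals.** The engine's complex treatment subtotal is
  €2,649.97 (presents €2,650) against a published €2,651, and the complex
  per-patient totals present €4,817/€4,317 against €4,818/€4,318: the
  source's internal cent values for this column are not recoverable from
  its printed inputs. These are reconciled within ±€1 and left as computed.
  One published sensitivity cell (typical not-pregnant high, printed equal
  to its own base) is internally inconsistent with every other cell's ±10%
  arithmetic and is treated as a typo; the engine computes €1,523 for it.
- **Degenerate inputs.** Empty scenarios cost €0 in every category; a
  pregnancy probability of 1 empties both not-pregnant subgroups; an empty
  program-item list totals €0. Zero-count or zero-minute contacts are
  rejected at construction.

## Synthetic data

`rmccost.synthetic` provides both the pinned reference dataset
(`paper_fixture`, transcribed into the packaged CSV/YAML files) and a
seeded random generator (`random_model`) that draws structurally identical
models — investigations, pack-priced courses, salary-derived staff rates,
contacts, program items, population shares — uniformly within configured
ranges. The generator emulates the *structure* of a clinic cost inventory,
not real price distributions, utilization heterogeneity or correlations
between items; passing property suites on generated models therefore
demonstrates arithmetic correctness (ledger/aggregate agreement, count
conservation, linearity, determinism) on well-formed inputs, not realism of
any particular cost estimate.

## Verification strategy

The itemized ledger (`itemized_ledger`) is a deliberately naive second
route to every per-patient total — one row per costed event, summed — and
the test and acceptance suites assert cent-exact agreement between it and
the category-aggregation route across 1,000+ seeded random models. The
budget stage is checked against explicit count × cost products, and the
reference dataset reconciles against its published headline figures
(program totals exactly; per-patient totals within the documented ±€1;
population-scale totals within 0.1%).

## Limitations

- The model costs one fixed pathway per archetype; real investigation and
  treatment mixes vary per patient.
- Prices are 2020/2021 euro levels with no indexing engine.
- Program costs assume a from-scratch setup of a single clinic; no cost
  offsets from existing services are modelled.
- The healthcare-system total scales per-patient costs linearly in head
  counts; capacity constraints (clinic sessions per month) are not fed back
  into the extrapolation.
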