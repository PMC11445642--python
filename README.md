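# rmccost

A micro-costing and budget-impact engine for a best-practice **recurrent
miscarriage clinic (RMC)** — a consultant-led outpatient service offering
investigations, treatment and bereavement support to women/couples after two
or more consecutive pregnancy losses.

The package is aimed at health economists and health-service researchers who
need a transparent, fully reproducible bottom-up costing of such a clinic:
every resource item (a blood test, a pack of aspirin, thirty minutes of an
obstetrician's time, a consultation-room fit-out) is priced individually, and
every headline figure is an audited sum over those items.

## The model

**Unit costs.** Staff time is valued per minute from loaded salaries:

```
loaded_annual = salary × (1 + PRSI + pension) × (1 + overheads)
rate_per_min  = loaded_annual / (weekly_hours × 60 × weeks_per_year)
```

with employer social insurance (11.05%), pension (4%) and institutional
overheads (25%) as defaults, a 39-hour week and 52 weeks/year. Drug courses
are priced from pack prices: a course of `w` weeks on a pack covering `d`
days costs `pack_price × 7w/d` (pro-rata), `pack_price × ⌈7w/d⌉`
(whole-pack), or a pinned published figure where the source's pack-count
convention is not recoverable.

**Per-patient pathway costs.** Two case archetypes — *typical* (90% of
cases) and *complex* (10%) — each itemise investigations, drug courses,
consultations and admin/care-coordination contacts, plus an outcome arm:
women who progress to another pregnancy receive reassurance ultrasound scans
(2 typical, 4 complex, €125 each); women who do not conceive again incur no
scan costs. All arithmetic is exact integer cents; whole-euro figures are
presentation views (round-half-up).

**Budget impact.** Per-patient costs are extrapolated to the eligible
population: 1,203,000 women of reproductive age × 5% prevalence of two or
more consecutive losses = 60,150 women, split 90/10 typical/complex and
70/30 pregnant/not-pregnant within each case type. Clinic setup
(one-off) and ongoing delivery costs (annual) are reported alongside.

**Sensitivity.** One-way deterministic analysis perturbs each block (setup
costs, delivery costs, each subgroup's per-patient cost and head count) by
±10% on its unrounded base, and ranks cost drivers by swing.

## Worked example

```python
from rmccost import paper_fixture, cost_model, per_patient_cost, program_total

bundle = paper_fixture()                # packaged reference dataset
print(program_total(bundle.program_items, "setup"))     # €37,321.00
print(program_total(bundle.program_items, "ongoing"))   # €12,212.00

pp = per_patient_cost(bundle.scenarios["typical"], "pregnant")
print(pp.total)                         # €1,634.19
print(pp.presentation)
# {'investigations': 983, 'treatment': 130, 'hcp_time': 136,
#  'admin_time': 136, 'outcome': 250, 'total': 1634}

result = cost_model(bundle).result()
print(result.grand_total)               # €112,530,251.34
print(result.average_per_patient_presented)  # 1871
```

Reading: setting up one clinic costs €37,321 once and €12,212 per year to
run; a typical patient who conceives again costs €1,634 (€983 of
investigations, €130 of drugs, €136 each of clinical and admin time, €250
of reassurance scans); scaled to the 60,150 eligible women the annual
patient-care bill is €112.5M, about €1,871 per patient.

The same tables are available from the shell:

```
rmccost report --out reports/ --format csv --format markdown
rmccost validate
```

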