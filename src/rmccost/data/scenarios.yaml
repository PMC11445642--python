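# Care-pathway scenario definitions for the two case archetypes.
# Contacts: one consultation per patient with the obstetrician (30 min
# typical, 60 min complex) and one 60-min bereavement-midwife consultation,
# plus one admin/care-coordination block each (obstetrician 30 min,
# midwife 60 min).  Outcome arms: 2 reassurance scans for a typical
# subsequent pregnancy, 4 for a complex one, at €125 per scan.
scenarios:
  typical:
    consultations:
      - {role: obstetrician, minutes: 30, count: 1}
      - {role: bereavement_midwife, minutes: 60, count: 1}
    admin:
      - {role: obstetrician, minutes: 30, count: 1}
      - {role: bereavement_midwife, minutes: 60, count: 1}
    outcomes:
      pregnant: {n_scans: 2, scan_price_eur: 125.00}
      not_pregnant: {n_scans: 0}
  complex:
    consultations:
      - {role: obstetrician, minutes: 60, count: 1}
      - {role: bereavement_midwife, minutes: 60, count: 1}
    admin:
      - {role: obstetrician, minutes: 30, count: 1}
      - {role: bereavement_midwife, minutes: 60, count: 1}
    outcomes:
      pregnant: {n_scans: 4, scan_price_eur: 125.00}
      not_pregnant: {n_scans: 0}
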