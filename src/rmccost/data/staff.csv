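role,per_minute_cost_eur,base_annual_salary_eur,prsi_rate,pension_rate,overhead_rate,weekly_hours
obstetrician,2.98,,0.1105,0.04,0.25,39
bereavement_midwife,0.77,,0.1105,0.04,0.25,39
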