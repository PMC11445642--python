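name,dose_label,duration_weeks,pack_price_eur,pack_cover_days,pack_policy,printed_cost_eur,typical,complex
folate,400mg,36,7.66,30,printed_override,65.11,1,1
aspirin_75mg,75mg,33,3.10,28,prorata,,1,0
aspirin_150mg,150mg,33,6.20,28,prorata,,0,1
progesterone_100mg,100mg,10,16.95,30,printed_override,39.00,1,0
progesterone_400mg,400mg,10,29.00,15,printed_override,136.00,0,1
low_molecular_weight_heparin,150mg syringe,34,98.20,10,prorata,,0,1
prednisolone,10mg,10,8.65,10,prorata,,0,1
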