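name,unit_cost_eur,typical,complex
full_blood_count,20.00,1,1
thyroid_function,10.00,1,1
hba1c_glucose,10.00,1,1
day_2_5_hormone,20.00,0,1
tv_ultrasound,200.00,1,1
pelvic_mri,240.00,0,1
ana_test,10.00,1,1
androgen_testing,20.00,1,1
dhea_s,63.39,0,1
aplas,10.00,1,1
pregnancy_tissue_histology,193.30,1,1
array_cgh,250.00,1,1
parental_karyotyping,260.00,1,1
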