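name,phase,units,unit_cost_eur,frequency_per_year
consultation_room_fitout,setup,2,8000.00,1
consumables_and_supplies,setup,2,10000.00,1
information_pack_development,setup,1,739.00,1
initial_training_materials,setup,1,370.00,1
initial_training_venue,setup,1,166.00,1
initial_training_trainer,setup,1,46.00,1
annual_training_venue,ongoing,1,166.00,1
annual_training_trainer,ongoing,1,46.00,1
clinic_space_rental,ongoing,1,250.00,48
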