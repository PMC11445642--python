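# Population inputs for the budget-impact extrapolation.
# 1,203,000 women of reproductive age (15-49), 5% prevalence of two or
# more consecutive first-trimester losses, 10% complex case share, 70%
# probability of progressing to another pregnancy.  The overrides pin the
# published headline subgroup counts (which are not exactly reproducible
# from the shares: independent rounding in the source breaks conservation);
# the derivation path remains available with overrides disabled.
reproductive_population: 1203000
rm_prevalence: 0.05
complex_share: 0.10
pregnancy_prob: 0.70
subgroup_overrides:
  typical_pregnant: 37895
  typical_not_pregnant: 16241
  complex_pregnant: 4221
  complex_not_pregnant: 1804
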