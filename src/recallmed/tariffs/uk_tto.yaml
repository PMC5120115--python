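# UK EQ-5D-3L time-trade-off value set (Dolan 1997).
# Utility = 1 - constant (if any dimension > level 1)
#             - sum of per-dimension decrements for the observed levels
#             - N3 (if any dimension is at level 3)
# Dimensions: MO mobility, SC self-care, UA usual activities,
# PD pain/discomfort, AD anxiety/depression.
full_health_value: 1.0
constant: 0.081
N3: 0.269
MO2: 0.069
MO3: 0.314
SC2: 0.104
SC3: 0.214
UA2: 0.036
UA3: 0.094
PD2: 0.123
PD3: 0.386
AD2: 0.071
AD3: 0.236
# Utility of state 33333 under the coefficients above.
min_utility: -0.594
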