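name,formula,kind
CO,CO,small
CO2,CO2,small
H2O,H2O,small
CH3,CH3,small
OH,OH,small
CHO,CHO,small
C2H2O,C2H2O,small
C5H9,C5H9,small
hexose,C6H10O5,conjugate
deoxyhexose,C6H10O4,conjugate
pentose,C5H8O4,conjugate
acetylhexose,C8H12O6,conjugate
acyl_C4H6O3,C4H6O3,conjugate
acetic_acid,C2H4O2,conjugate
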