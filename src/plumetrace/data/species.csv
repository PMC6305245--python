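label,formula,mass_u,charge,nominal_mz
(CHCA)H+,C10H8NO3,190.0499,1,190
(CHCA)2H+,C20H15N2O6,379.0925,1,379
(CHCA)Na+,C10H7NO3Na,212.0318,1,212
(CHCA-H2O)H+,C10H6NO2,172.0393,1,172
CHCA,C10H7NO3,189.0426,1,189
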