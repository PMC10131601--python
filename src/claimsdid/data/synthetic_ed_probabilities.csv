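diag_code,p_emergent,p_nonemergent,p_other,frequency
R07.9,0.55,0.40,0.05,0.080
R10.9,0.35,0.60,0.05,0.075
J06.9,0.05,0.90,0.05,0.090
S93.40,0.15,0.80,0.05,0.060
R51.9,0.20,0.70,0.10,0.050
N39.0,0.25,0.70,0.05,0.055
J45.901,0.60,0.35,0.05,0.040
I21.9,0.95,0.00,0.05,0.015
R06.02,0.65,0.30,0.05,0.045
A09,0.20,0.75,0.05,0.040
S52.501,0.70,0.20,0.10,0.025
R55,0.50,0.40,0.10,0.030
K35.80,0.90,0.05,0.05,0.010
L03.90,0.30,0.65,0.05,0.035
M54.50,0.10,0.85,0.05,0.070
R42,0.40,0.50,0.10,0.040
T78.40,0.45,0.45,0.10,0.020
J18.9,0.75,0.15,0.10,0.020
G43.909,0.35,0.55,0.10,0.045
S01.81,0.40,0.50,0.10,0.030
F41.9,0.25,0.60,0.15,0.045
R50.9,0.30,0.60,0.10,0.080
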