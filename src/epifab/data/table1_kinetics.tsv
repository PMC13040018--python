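label	variable_chains	ka	kd	KD_reported_nM
A1	VH + VL	3.38E+05	8.55E-04	2.53
A2	VH1 + VL1	2.09E+05	9.48E-04	4.53
A3	VH1 + VL2	1.89E+05	1.01E-03	5.35
A4	VH1 + VL3	2.85E+05	9.18E-04	3.22
A5	VH2 + VL1	2.01E+05	8.86E-04	4.4
A6	VH2 + VL2	1.86E+05	7.08E-04	3.81
A7	VH2 + VL3	2.20E+05	8.70E-04	3.95
A8	VH3 + VL1	2.06E+05	6.66E-04	3.24
A9	VH3 + VL2	1.90E+05	7.29E-04	3.84
A10	VH3 + VL3	2.44E+05	6.16E-04	2.53
B1	VH + VL-DA	3.74E+05	7.46E-04	2
B2	VH + VL-EG	3.63E+05	8.92E-04	2.46
B3	VH2 + VL2-DA	2.08E+05	8.27E-04	3.97
B4	VH2 + VL1-DA	2.41E+05	7.16E-04	2.97
B5	VH3 + VL1-DA	2.34E+05	5.95E-04	2.54
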