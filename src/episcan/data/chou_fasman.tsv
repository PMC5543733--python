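# name: chou-fasman
# source: Chou PY & Fasman GD (1978) Adv Enzymol 47:45-148
# columns: residue, P_alpha, P_beta, P_turn, f(i), f(i+1), f(i+2), f(i+3)
# note: P values are conformational propensities (1.0 = average); f values are
# note: positional bend frequencies used in the tetrapeptide turn product
A	1.42	0.83	0.66	0.060	0.076	0.035	0.058
C	0.70	1.19	1.19	0.149	0.050	0.117	0.128
D	1.01	0.54	1.46	0.147	0.110	0.179	0.081
E	1.51	0.37	0.74	0.056	0.060	0.077	0.064
F	1.13	1.38	0.60	0.059	0.041	0.065	0.065
G	0.57	0.75	1.56	0.102	0.085	0.190	0.152
H	1.00	0.87	0.95	0.140	0.047	0.093	0.054
I	1.08	1.60	0.47	0.043	0.034	0.013	0.056
K	1.16	0.74	1.01	0.055	0.115	0.072	0.095
L	1.21	1.30	0.59	0.061	0.025	0.036	0.070
M	1.45	1.05	0.60	0.068	0.082	0.014	0.055
N	0.67	0.89	1.56	0.161	0.083	0.191	0.091
P	0.57	0.55	1.52	0.102	0.301	0.034	0.068
Q	1.11	1.10	0.98	0.074	0.098	0.037	0.098
R	0.98	0.93	0.95	0.070	0.106	0.099	0.085
S	0.77	0.75	1.43	0.120	0.139	0.125	0.106
T	0.83	1.19	0.96	0.086	0.108	0.065	0.079
V	1.06	1.70	0.50	0.062	0.048	0.028	0.053
W	1.08	1.37	0.96	0.077	0.013	0.064	0.167
Y	0.69	1.47	1.14	0.082	0.065	0.114	0.125
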