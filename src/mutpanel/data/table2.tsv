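# GA-selection predictions: 22 candidate harmful mutations with
# column-average degree, betweenness, closeness (x 1e-4) and relative
# accessibility.
mutation	deg_avg	bet_avg	clo_avg_e4	acc_avg
I20A	8.45	728.61	8.2	3.12
R26A	6.76	236.21	7.69	33.79
Y49T	6.8	227.64	7.68	23.21
S50A	9.26	565.23	8.52	0.33
L53A	6.76	138.71	7.45	36.94
K56G	6.87	198.56	7.64	16.32
V59I	7.63	537.69	8.49	5.7
T60K	5.25	455.12	9.01	25.92
A66C	7.12	1016.93	9.32	3.35
V80P	9.2	719.95	8.77	1.19
W90Y	6.96	1275.57	10.24	6.37
F115H	6.48	416.05	8.57	22.09
Q119H	6.21	165.8	8.22	27.2
G122K	5.22	485.78	9.66	16.62
L147T	9.48	808.43	9.23	0.47
V150L	10.96	1109.65	9.48	0.67
E153G	5.91	120.75	7.98	40.56
L204V	9.26	1076.06	9.87	3.06
N213K	5.72	265.96	8.09	37.79
G214P	4.09	108.98	7.57	31.33
V226I	9.31	787.96	9.6	1.76
V241L	7.29	518.77	8.31	16.84
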