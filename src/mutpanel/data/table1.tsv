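# Manual-selection predictions: 22 candidate harmful mutations with
# column-average degree, betweenness, closeness (x 1e-4) and relative
# accessibility.
mutation	deg_avg	bet_avg	clo_avg_e4	acc_avg
S19E	3.93	101.68	9.9	47.47
I20A	8.45	728.61	9.9	3.12
N28K	5.54	93.93	9.9	30.09
K56G	6.87	198.56	9.9	16.32
T60K	5.25	455.12	9.8	25.92
K69E	4.57	362.98	10.0	39.75
S71K	2.86	160.55	9.7	69.87
K89D	3.82	289.67	9.9	44.37
D111K	5.08	89.62	9.8	44.26
G118E	3.53	19.84	9.8	78.12
E152A	3.8	22.26	9.9	73.91
E153G	5.91	120.75	9.9	40.56
K155D	3.49	23.58	9.8	74.42
T158K	4.39	100.68	9.9	60.49
S194E	4.37	26.71	9.9	74.15
K195N	4.61	49.99	9.9	55.2
K199E	3.56	56.41	9.9	64.94
S202E	4.35	100.48	9.9	52.74
N213K	5.72	265.96	9.9	37.79
G214P	4.09	108.98	9.9	31.33
K221A	5.24	246.48	10.0	19.78
D222A	4.89	56.55	9.9	68.43
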