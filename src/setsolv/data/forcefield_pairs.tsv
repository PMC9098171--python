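bead1	bead2	a	R
C2	C2	22.0	1.074
EO	EO	25.5	1.116
OH	OH	14.0	0.980
OHp	OHp	14.0	0.949
W	W	25.0	1.000
T	T	24.0	0.955
T2	T2	24.0	1.098
ACp	ACp	22.5	0.952
AM3	AM3	22.0	1.296
OH2	OH2	18.0	1.012
C2	EO	23.78	1.095
C2	OH	27.13	1.027
C2	W	45.54	1.037
C2	OHp	28.77	1.012
C2	AM3	21.83	1.185
C2	ACp	18.17	1.013
C2	T2	21.97	1.086
OHp	AM3	11.00	1.123
OHp	OH	13.86	0.965
OHp	OH2	15.95	0.981
OHp	ACp	19.42	0.951
OHp	T	28.85	0.952
OHp	T2	28.28	1.024
OHp	W	15.09	0.975
EO	OH	18.17	1.048
EO	W	21.81	1.058
OH	W	18.17	0.990
OH	AM3	11.52	1.138
OH2	ACp	17.42	0.982
T	W	46.35	0.978
T	OH	27.49	0.968
T	C2	22.92	1.015
T	EO	24.18	1.036
T	AM3	22.32	1.126
W	OH2	22.20	1.006
W	ACp	7.74	0.976
W	AM3	13.20	1.148
W	T2	45.44	1.049
T2	ACp	17.32	1.025
T2	OH2	27.59	1.024
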