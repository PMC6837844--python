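variant	steady_state_pct	ddg_kcal_mol	clinvar_class	dme
E23D	90.0	0.49	VUS	3
I25T	51.3	2.40	VUS	3
A29S	109.6	2.06	likely_pathogenic	3
M35R	72.1	3.52	likely_pathogenic	0
I36S	63.2	4.08	VUS	NA
N38D	63.5	1.61	VUS	2
S44F	9.8	>15	likely_pathogenic	0
S44A	103.2	-1.35	VUS	3
G54E	15.3	>15	VUS	1
N64S	96.3	2.16	VUS	1
G67R	35.0	>15	likely_pathogenic	0
G67W	14.5	>15	likely_pathogenic	0
I68N	62.5	2.22	likely_pathogenic	0
R69K	104.9	-0.18	VUS	3
C77Y	61.0	6.57	likely_pathogenic	2
F80V	72.3	2.22	likely_pathogenic	1
T82I	100.0	0.54	likely_pathogenic	2
R100P	46.4	-1.25	likely_pathogenic	2
E102D	97.9	0.34	likely_pathogenic	3
A111V	68.8	4.96	likely_pathogenic	0
T117M	32.8	7.14	likely_pathogenic	0
T117R	46.2	12.70	likely_pathogenic	0
A128P	62.8	2.40	likely_pathogenic	0
D132H	110.2	-0.30	likely_benign	3
A160V	107.3	0.38	VUS	3
R182G	87.9	2.60	likely_pathogenic	3
S193P	100.7	2.73	VUS	0
V213M	103.9	-0.81	likely_benign	3
R217C	74.1	1.06	VUS	2
I219V	112.5	0.66	likely_benign	3
I219L	121.9	-0.05	likely_benign	3
R226L	63.3	0.27	likely_pathogenic	1
G244V	32.0	>15	VUS	0
G244D	38.8	>15	likely_pathogenic	0
H264R	117.6	-0.60	VUS	3
R265C	57.2	0.28	likely_pathogenic	2
R265H	81.4	0.04	VUS	3
E268G	81.1	0.81	likely_benign	2
L272V	80.0	1.95	VUS	3
A281V	82.5	0.87	likely_pathogenic	3
K286Q	101.8	0.28	VUS	2
S295G	88.6	0.13	likely_pathogenic	2
H329P	54.1	5.67	likely_pathogenic	1
V506A	62.1	2.18	VUS	2
Q542L	110.2	-1.56	VUS	3
L549P	63.7	5.17	VUS	0
I565F	65.9	9.64	VUS	0
L574P	34.4	11.97	likely_pathogenic	0
E578G	103.2	0.45	likely_benign	2
L582V	100.0	1.93	VUS	3
L588P	88.6	3.30	VUS	1
K618A	80.4	0.61	VUS	1
K618T	106.5	0.09	likely_benign	0
L622H	61.1	4.97	likely_pathogenic	0
P640T	61.1	3.78	VUS	0
L653R	66.1	3.22	likely_pathogenic	0
I655V	89.1	1.03	likely_benign	3
I655T	71.1	1.29	VUS	3
R659P	69.0	6.93	likely_pathogenic	0
R659Q	84.9	2.41	VUS	2
T662P	72.7	5.23	likely_pathogenic	0
E663G	72.0	-0.23	VUS	3
E663D	97.2	0.66	likely_pathogenic	2
L676R	36.8	5.12	VUS	0
R687W	115.4	1.12	likely_pathogenic	0
Q689R	71.0	-0.54	likely_benign	3
V716M	100.1	1.41	likely_benign	1
H718Y	73.7	0.16	likely_benign	2
K751R	82.1	-0.23	likely_benign	3
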