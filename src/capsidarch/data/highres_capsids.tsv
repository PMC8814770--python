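# High-resolution tailed-phage capsid database: 37 phages with solved capsid
# structures, their triangulation number and genome length in kilobase pairs.
# Lattice is "trihexagonal" where the solved structure shows the trimer-bearing
# lattice, "hexagonal" where the classic lattice is established, and
# "unspecified" where the structural lattice class is not recorded here.
phage	t_value	lattice	genome_kbp
C1	4	hexagonal	16.7
HSTV-1	7	hexagonal	32.2
P27	7	hexagonal	33.6
TP901-1	7	hexagonal	37.7
Sf6	7	hexagonal	39.0
epsilon15	7	hexagonal	39.7
HK97	7	hexagonal	39.7
T7	7	hexagonal	39.9
CUS-3	7	hexagonal	40.2
HK022	7	hexagonal	40.8
Pf-WMP4	7	hexagonal	40.9
BPP-1	7	hexagonal	42.9
P22	7	hexagonal	43.5
80alpha	7	hexagonal	43.9
K1E/K1-5	7	hexagonal	44.7
P-SSP7	7	hexagonal	45.0
Gifsy-2	7	hexagonal	45.8
Syn5	7	hexagonal	46.2
lambda	7	hexagonal	48.5
CW02	7	hexagonal	49.4
SPP1	7	hexagonal	49.5
SIO-2	12	unspecified	80.0
Basilisk	12	trihexagonal	81.8
P74-26	9.33	trihexagonal	83.0
P23-45	9.33	trihexagonal	84.2
Mic1	13	hexagonal	92.6
T5	13	hexagonal	121.8
SPO1	16	hexagonal	132.6
phiM12	19	hexagonal	194.7
N3	19	hexagonal	207.0
PAU	25	unspecified	219.0
phiRSL1	27	hexagonal	240.0
PBS1	27	unspecified	252.0
phiKZ	27	hexagonal	280.0
121Q	28	unspecified	348.5
SCTP2	39	unspecified	440.0
G	52	hexagonal	498.0
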