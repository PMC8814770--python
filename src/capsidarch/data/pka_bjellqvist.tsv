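# Bjellqvist pKa set for protein isoelectric-point calculation
# (Bjellqvist et al. 1993, Electrophoresis 14:1023-1031; values as used by
# the ExPASy Compute pI tool). group: residue one-letter code, or the
# terminal groups "Nterm" / "Cterm". sign: +1 for groups that are positively
# charged when protonated (N-terminus, K, R, H), -1 for groups that are
# negatively charged when deprotonated (C-terminus, D, E, C, Y).
group	pka	sign
Nterm	7.50	+1
K	10.00	+1
R	12.00	+1
H	5.98	+1
Cterm	3.55	-1
D	4.05	-1
E	4.45	-1
C	9.00	-1
Y	10.00	-1
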