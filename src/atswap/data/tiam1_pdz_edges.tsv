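# Swap-based relative binding free energy estimates (kcal/mol, 1 sigma)
# for the TIAM-1 PDZ domain binding the wild-type Syndecan-1 peptide
# (WT) and its A0M / A0V / A0F single-point mutants, both alchemical
# directions of every pair.
from	to	ddG	sigma
WT	A0M	1.74	0.26
A0M	WT	-1.57	0.26
WT	A0V	1.92	0.78
A0V	WT	-2.63	0.20
WT	A0F	2.17	0.28
A0F	WT	-1.30	0.28
A0M	A0F	0.68	0.28
A0F	A0M	-0.17	0.28
A0V	A0F	-0.54	0.26
A0F	A0V	0.28	0.26
A0M	A0V	0.14	0.24
A0V	A0M	-1.18	0.24
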