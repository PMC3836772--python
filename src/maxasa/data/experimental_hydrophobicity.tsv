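# Experimental hydrophobicity scales (literature data, one column per scale).
# kyte_doolittle: hydropathy index (Kyte & Doolittle 1982, J Mol Biol 157:105).
# fauchere_pliska: side-chain octanol/water transfer free energy pi
#   (Fauchere & Pliska 1983, Eur J Med Chem 18:369).
aa	kyte_doolittle	fauchere_pliska
A	1.8	0.31
R	-4.5	-1.01
N	-3.5	-0.60
D	-3.5	-0.77
C	2.5	1.54
E	-3.5	-0.64
Q	-3.5	-0.22
G	-0.4	0.00
H	-3.2	0.13
I	4.5	1.80
L	3.8	1.70
K	-3.9	-0.99
M	1.9	1.23
F	2.8	1.79
P	-1.6	0.72
S	-0.8	-0.04
T	-0.7	0.26
W	-0.9	2.25
Y	-1.3	0.96
V	4.2	1.22
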