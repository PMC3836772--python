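aa	residue	theoretical	empirical	miller1987	rose1985
A	Alanine	129.0	121.0	113.0	118.1
R	Arginine	274.0	265.0	241.0	256.0
N	Asparagine	195.0	187.0	158.0	165.5
D	Aspartate	193.0	187.0	151.0	158.7
C	Cysteine	167.0	148.0	140.0	146.1
E	Glutamate	223.0	214.0	183.0	186.2
Q	Glutamine	225.0	214.0	189.0	193.2
G	Glycine	104.0	97.0	85.0	88.1
H	Histidine	224.0	216.0	194.0	202.5
I	Isoleucine	197.0	195.0	182.0	181.0
L	Leucine	201.0	191.0	180.0	193.1
K	Lysine	236.0	230.0	211.0	225.8
M	Methionine	224.0	203.0	204.0	203.4
F	Phenylalanine	240.0	228.0	218.0	222.8
P	Proline	159.0	154.0	143.0	146.8
S	Serine	155.0	143.0	122.0	129.8
T	Threonine	172.0	163.0	146.0	152.5
W	Tryptophan	285.0	264.0	259.0	266.3
Y	Tyrosine	263.0	255.0	229.0	236.8
V	Valine	174.0	165.0	160.0	164.5
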