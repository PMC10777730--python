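# Per-residue aggregation-propensity scale (a3v), transcribed from the
# experimentally derived amino-acid scale of Conchillo-Sole et al.,
# BMC Bioinformatics 2007, 8:65 (Table 1).  Dimensionless.
# residue	value
A	-0.036
C	0.604
D	-1.836
E	-1.412
F	1.754
G	-0.535
H	-1.033
I	1.822
K	-0.931
L	1.380
M	0.910
N	-0.776
P	-2.303
Q	-0.276
R	-1.240
S	-0.294
T	-0.159
V	1.594
W	1.037
Y	1.159
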