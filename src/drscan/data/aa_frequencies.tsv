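# Amino-acid composition used for synthetic mitochondrial protein-coding
# genes: a plausible average for vertebrate mtDNA-encoded (membrane-rich,
# Leu/Ile/Thr-heavy) proteins. Override via GenomeSpec.aa_frequencies.
aa	frequency
L	0.165
I	0.095
T	0.085
A	0.070
S	0.070
F	0.055
V	0.055
M	0.050
P	0.050
N	0.045
G	0.045
Y	0.035
W	0.030
H	0.025
Q	0.025
K	0.025
E	0.025
R	0.020
D	0.020
C	0.010
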