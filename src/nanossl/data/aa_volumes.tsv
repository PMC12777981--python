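# Amino-acid residue volumes (nm^3), from A.A. Zamyatnin,
# "Protein volume in solution", Prog. Biophys. Mol. Biol. 24:107-123 (1972).
# One-letter code <TAB> volume_nm3
A	0.0886
R	0.1734
N	0.1141
D	0.1111
C	0.1085
Q	0.1438
E	0.1384
G	0.0601
H	0.1532
I	0.1667
L	0.1667
K	0.1686
M	0.1629
F	0.1899
P	0.1127
S	0.0890
T	0.1161
W	0.2278
Y	0.1936
V	0.1400
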