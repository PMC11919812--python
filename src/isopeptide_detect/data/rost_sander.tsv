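# Maximum accessible surface area per residue type (Angstrom^2),
# Rost & Sander normalization values.
# res_name	max_asa
ALA	106.0
ARG	248.0
ASN	157.0
ASP	163.0
CYS	135.0
GLN	198.0
GLU	194.0
GLY	84.0
HIS	184.0
ILE	169.0
LEU	164.0
LYS	205.0
MET	188.0
PHE	197.0
PRO	136.0
SER	130.0
THR	142.0
TRP	227.0
TYR	222.0
VAL	142.0
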