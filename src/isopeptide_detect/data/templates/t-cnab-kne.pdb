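REMARK 400 ISOPEP id=t-cnab-kne topology=CnaB-like triad_type=Lys-Asn-Glu flank=CTCECEGLNRDGHKHMAREASSYTWAPHYAISKKNELYTAIIF
ATOM      1  CB  LYS A   1       1.994   1.433   0.000  1.00  0.00           C
ATOM      2  CG  LYS A   1       3.511   1.526   0.000  1.00  0.00           C
ATOM      3  CD  LYS A   1       3.981   2.972  -0.000  1.00  0.00           C
ATOM      4  CE  LYS A   1       5.498   3.064   0.000  1.00  0.00           C
ATOM      5  NZ  LYS A   1       5.964   4.458  -0.000  1.00  0.00           N
ATOM      6  CB  GLU B   2       4.804   4.277   4.972  1.00  0.00           C
ATOM      7  CG  GLU B   2       4.756   4.464   3.464  1.00  0.00           C
ATOM      8  CD  GLU B   2       4.639   5.928   3.075  1.00  0.00           C
ATOM      9  OE1 GLU B   2       4.591   6.210   1.858  1.00  0.00           O
ATOM     10  OE2 GLU B   2       4.593   6.809   3.962  1.00  0.00           O
ATOM     11  CB  ASN C   3       5.343   4.566  -2.326  1.00  0.00           C
ATOM     12  CG  ASN C   3       5.911   5.219  -1.089  1.00  0.00           C
ATOM     13  OD1 ASN C   3       6.307   6.384  -1.069  1.00  0.00           O
END
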