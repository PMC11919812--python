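REMARK 400 ISOPEP id=t-cnaa-kde topology=CnaA-like triad_type=Lys-Asp-Glu flank=YMTMCGPWWGADLKVAYFDTMTFMVSMQYKNFHSSQICRPTGS
ATOM      1  CB  LYS A   1       1.994   1.433   0.000  1.00  0.00           C
ATOM      2  CG  LYS A   1       3.511   1.526   0.000  1.00  0.00           C
ATOM      3  CD  LYS A   1       3.981   2.972  -0.000  1.00  0.00           C
ATOM      4  CE  LYS A   1       5.498   3.064   0.000  1.00  0.00           C
ATOM      5  NZ  LYS A   1       5.964   4.458  -0.000  1.00  0.00           N
ATOM      6  CB  GLU B   2       1.759   5.296   2.778  1.00  0.00           C
ATOM      7  CG  GLU B   2       2.752   5.134   1.639  1.00  0.00           C
ATOM      8  CD  GLU B   2       3.055   6.458   0.956  1.00  0.00           C
ATOM      9  OE1 GLU B   2       3.861   6.455  -0.000  1.00  0.00           O
ATOM     10  OE2 GLU B   2       2.505   7.507   1.354  1.00  0.00           O
ATOM     11  CB  ASP C   3       7.124   6.397  -0.840  1.00  0.00           C
ATOM     12  CG  ASP C   3       6.723   4.948  -0.977  1.00  0.00           C
ATOM     13  OD1 ASP C   3       7.065   4.244  -1.926  1.00  0.00           O
END
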