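REMARK   2 RESOLUTION. 1.50 ANGSTROMS.
ATOM      1  N   ASP A  25       1.000   0.500   0.200  1.00 10.00           N
ATOM      2  CA  ASP A  25       2.200   1.100   0.600  1.00 11.00           C
ATOM      3  C   ASP A  25       3.400   0.300   0.100  1.00 12.00           C
ATOM      4  O   ASP A  25       3.500  -0.900   0.300  1.00 13.00           O
ATOM      5  CB  ASP A  25       2.300   2.500   0.000  1.00 14.00           C
ATOM      6  CG  ASP A  25       1.400   3.500   0.700  1.00 15.00           C
ATOM      7  OD1 ASP A  25       0.500   3.100   1.500  1.00 16.00           O
ATOM      8  OD2 ASP A  25       1.000   2.000   3.000  1.00 17.00           O
ATOM      9  N   GLY A  26       4.400   0.900  -0.500  1.00 18.00           N
ATOM     10  CA  GLY A  26       5.600   0.200  -0.900  1.00 19.00           C
HETATM   11  O   HOH A 101       6.000   5.000   2.000  1.00 30.00           O
HETATM   12  O   HOH A 102       7.500   6.500   3.500  1.00 31.00           O
END
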