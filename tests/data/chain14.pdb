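REMARK   2 RESOLUTION. 2.10 ANGSTROMS.
HELIX    1   1 HIS A    5  THR A   10  1                                   6
SHEET    1   A 2 PHE A  12  TYR A  13  0
ATOM      1  CA  MET A   1       3.800   0.000   0.000  1.00 20.00           C
ATOM      2  CA  ALA A   2       7.600   0.000   0.000  1.00 20.00           C
ATOM      3  CA  ASP A   3      11.400   0.000   0.000  1.00 20.00           C
ATOM      4  CA  GLY A   4      15.200   0.000   0.000  1.00 20.00           C
ATOM      5  CA  HIS A   5      19.000   0.000   0.000  1.00 20.00           C
ATOM      6  CA  LEU A   6      22.800   0.000   0.000  1.00 20.00           C
ATOM      7  CA  LYS A   7      26.600   0.000   0.000  1.00 20.00           C
ATOM      8  CA  MSE A   8      30.400   0.000   0.000  1.00 20.00           C
ATOM      9  CA  SER A   9      34.200   0.000   0.000  1.00 20.00           C
ATOM     10  CA  THR A  10      38.000   0.000   0.000  1.00 20.00           C
ATOM     11  CA  VAL A  11      41.800   0.000   0.000  1.00 20.00           C
ATOM     12  CA  PHE A  12      45.600   0.000   0.000  1.00 20.00           C
ATOM     13  CA  TYR A  13      49.400   0.000   0.000  1.00 20.00           C
ATOM     14  CA  GLU A  14      53.200   0.000   0.000  1.00 20.00           C
END
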