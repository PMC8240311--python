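ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.422   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.917   1.746  -0.766  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.768  -1.201  1.00  0.00           C
ATOM      6  N   ASP A   2       1.455   2.266   0.864  1.00  0.00           N
ATOM      7  CA  ASP A   2       1.890   3.654   0.965  1.00  0.00           C
ATOM      8  C   ASP A   2       1.759   4.372  -0.374  1.00  0.00           C
ATOM      9  O   ASP A   2       2.692   5.035  -0.828  1.00  0.00           O
ATOM     10  CB  ASP A   2       3.327   3.725   1.459  1.00  0.00           C
ATOM     11  N   GLU A   3       0.596   4.236  -1.002  1.00  0.00           N
ATOM     12  CA  GLU A   3       0.341   4.871  -2.289  1.00  0.00           C
ATOM     13  C   GLU A   3       1.359   4.428  -3.334  1.00  0.00           C
ATOM     14  O   GLU A   3       1.945   5.254  -4.033  1.00  0.00           O
ATOM     15  CB  GLU A   3       0.361   6.385  -2.147  1.00  0.00           C
ATOM     16  N   PHE A   4       1.565   3.118  -3.435  1.00  0.00           N
ATOM     17  CA  PHE A   4       2.512   2.563  -4.394  1.00  0.00           C
ATOM     18  C   PHE A   4       3.908   3.144  -4.190  1.00  0.00           C
ATOM     19  O   PHE A   4       4.585   3.509  -5.150  1.00  0.00           O
ATOM     20  CB  PHE A   4       2.040   2.821  -5.816  1.00  0.00           C
ATOM     21  N   ILE A   5       4.331   3.226  -2.932  1.00  0.00           N
ATOM     22  CA  ILE A   5       5.646   3.762  -2.600  1.00  0.00           C
ATOM     23  C   ILE A   5       5.808   5.186  -3.120  1.00  0.00           C
ATOM     24  O   ILE A   5       6.813   5.517  -3.749  1.00  0.00           O
ATOM     25  CB  ILE A   5       6.740   2.870  -3.165  1.00  0.00           C
ATOM     26  N   LYS A   6       4.812   6.025  -2.852  1.00  0.00           N
ATOM     27  CA  LYS A   6       4.843   7.415  -3.292  1.00  0.00           C
ATOM     28  C   LYS A   6       5.035   7.512  -4.802  1.00  0.00           C
ATOM     29  O   LYS A   6       5.852   8.295  -5.284  1.00  0.00           O
ATOM     30  CB  LYS A   6       5.947   8.175  -2.573  1.00  0.00           C
ATOM     31  N   LEU A   7       4.275   6.711  -5.542  1.00  0.00           N
ATOM     32  CA  LEU A   7       4.360   6.705  -6.998  1.00  0.00           C
ATOM     33  C   LEU A   7       5.781   6.409  -7.466  1.00  0.00           C
ATOM     34  O   LEU A   7       6.325   7.116  -8.315  1.00  0.00           O
ATOM     35  CB  LEU A   7       3.888   8.036  -7.562  1.00  0.00           C
ATOM     36  N   MET A   8       6.378   5.362  -6.907  1.00  0.00           N
ATOM     37  CA  MET A   8       7.736   4.971  -7.266  1.00  0.00           C
ATOM     38  C   MET A   8       8.717   6.116  -7.040  1.00  0.00           C
ATOM     39  O   MET A   8       9.915   5.978  -7.287  1.00  0.00           O
ATOM     40  CB  MET A   8       7.790   4.512  -8.715  1.00  0.00           C
TER
END
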