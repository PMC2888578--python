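# Minimal extended-atom parameter set for peptide-scaffold complexes.
#
# Format (documented in docs/methods.md):
#   [options]                key = value pairs
#   [atomtypes]              TYPE  rstar(A)  eps(kcal/mol)
#   [bonds]                  T1 T2  k(kcal/mol/A^2)  r0(A)        E = k (r-r0)^2
#   [angles]                 T1 T2 T3  k(kcal/mol/rad^2) theta0(deg); X = wildcard
#   [dihedrals]              T1 T2 T3 T4  V/2(kcal/mol) n gamma(deg); X = wildcard,
#                            several lines per central pair accumulate
#   [residue NAME]           ATOM  TYPE  charge(e); optional "form=NAME" variants
#
# Charges are a reduced, internally consistent set (each residue form sums to an
# integer); they are NOT the ff96/RESP charges, which can be dropped in by
# replacing the residue blocks of this file.

[options]
coulomb_constant = 332.0636
scale_ee_14 = 1.2
scale_vdw_14 = 2.0
combination_rule = lorentz-berthelot

[atomtypes]
CT  2.000  0.1200
C   1.908  0.0860
CA  1.950  0.1000
N   1.824  0.1700
O   1.661  0.2100
O2  1.661  0.2100
OH  1.721  0.2104
OS  1.684  0.1700
P   2.100  0.2000
S   2.000  0.2500
SH  2.000  0.2500
XB  1.700  0.1500
XP  1.900  0.1700
XN  1.700  0.2100

[bonds]
CT CT  310.0  1.526
CT C   317.0  1.522
C  N   490.0  1.335
N  CT  337.0  1.449
C  O   570.0  1.229
C  O2  656.0  1.250
CT OH  320.0  1.410
C  OH  400.0  1.357
CT OS  320.0  1.410
CA CA  469.0  1.400
CA CT  317.0  1.510
CA N   427.0  1.381
CA OH  450.0  1.364
CA OS  450.0  1.364
OS P   230.0  1.610
P  O2  525.0  1.480
CT S   227.0  1.810
CT SH  237.0  1.810

[angles]
X CT X  40.0  109.5
X C  X  70.0  120.0
X CA X  63.0  120.0
X N  X  50.0  120.0
X OS X  60.0  120.0
X OH X  55.0  108.5
X P  X  45.0  109.5
X S  X  62.0   98.9
X SH X  43.0   96.0

[dihedrals]
X CT CT X  0.156  3    0.0
X CT C  X  0.000  2  180.0
X C  N  X  10.00  2  180.0
X N  CT X  0.000  2  180.0
X CT CA X  0.000  2  180.0
X CA CA X  3.625  2  180.0
X CA N  X  1.800  2  180.0
X CA OS X  1.800  2  180.0
X CA OH X  0.900  2  180.0
X OS P  X  0.250  3    0.0
X CT OH X  0.167  3    0.0
X C  OH X  0.900  2  180.0
X CT OS X  0.383  3    0.0
X CT S  X  0.333  3    0.0
X CT SH X  0.250  3    0.0

# ---------------------------------------------------------------- residues
# Backbone charge motif: N -0.40, CA +0.25, C +0.60, O -0.45 (sums to 0).

[residue ALA]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00

[residue GLY]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45

[residue VAL]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG1 CT  0.00
CG2 CT  0.00

[residue LEU]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD1 CT  0.00
CD2 CT  0.00

[residue ILE]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG1 CT  0.00
CG2 CT  0.00
CD1 CT  0.00

[residue SER]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.25
OG OH  -0.25

[residue THR]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.25
OG1 OH -0.25
CG2 CT  0.00

[residue CYS]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.15
SG SH  -0.15

[residue MET]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.10
SD S   -0.20
CE CT   0.10

[residue PHE]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CA   0.00
CD1 CA  0.00
CD2 CA  0.00
CE1 CA  0.00
CE2 CA  0.00
CZ CA   0.00

[residue TYR]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CA   0.00
CD1 CA  0.00
CD2 CA  0.00
CE1 CA  0.00
CE2 CA  0.00
CZ CA   0.25
OH OH  -0.25

[residue TRP]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CA   0.00
CD1 CA  0.10
CD2 CA  0.00
NE1 N  -0.20
CE2 CA  0.10
CE3 CA  0.00
CZ2 CA  0.00
CZ3 CA  0.00
CH2 CA  0.00

[residue HIS]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CA   0.10
ND1 N  -0.30
CD2 CA  0.10
CE1 CA  0.25
NE2 N  -0.15

[residue PRO]
N  N  -0.55
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD CT   0.15

[residue ASN]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG C    0.55
OD1 O  -0.50
ND2 N  -0.05

[residue GLN]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD C    0.55
OE1 O  -0.50
NE2 N  -0.05

[residue ASP]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT  -0.10
CG C    0.62
OD1 O2 -0.76
OD2 O2 -0.76

[residue ASP form=neutral]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG C    0.55
OD1 O  -0.45
OD2 OH -0.10

[residue GLU]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT  -0.10
CD C    0.62
OE1 O2 -0.76
OE2 O2 -0.76

[residue GLU form=neutral]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD C    0.55
OE1 O  -0.45
OE2 OH -0.10

[residue LYS]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD CT   0.00
CE CT   0.25
NZ N    0.75

[residue LYS form=neutral]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD CT   0.00
CE CT   0.20
NZ N   -0.20

[residue ARG]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD CT   0.10
NE N   -0.10
CZ CA   0.60
NH1 N   0.20
NH2 N   0.20

[residue ARG form=neutral]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CT   0.00
CD CT   0.10
NE N   -0.25
CZ CA   0.40
NH1 N  -0.125
NH2 N  -0.125

# Phosphotyrosine; default form is the di-anionic phosphate (net -2),
# the mono-anionic variant is selectable by configuration.
[residue PTR]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CA   0.00
CD1 CA  0.00
CD2 CA  0.00
CE1 CA  0.00
CE2 CA  0.00
CZ CA   0.35
OH OS  -0.45
P  P    1.40
O1P O2 -1.10
O2P O2 -1.10
O3P O2 -1.10

[residue PTR form=monoanionic]
N  N  -0.40
CA CT  0.25
C  C    0.60
O  O   -0.45
CB CT   0.00
CG CA   0.00
CD1 CA  0.00
CD2 CA  0.00
CE1 CA  0.00
CE2 CA  0.00
CZ CA   0.35
OH OS  -0.40
P  P    1.35
O1P O2 -0.90
O2P O2 -0.90
O3P O2 -0.50

[residue ACE]
CH3 CT -0.05
C  C    0.55
O  O   -0.50

[residue NME]
N  N  -0.40
CH3 CT  0.40

# Synthetic-scaffold pseudo-residues: apolar pocket bead, cationic
# anchor site (pocket-arginine analogue, keeps its full charge), and
# polar shelf bead.
[residue SCB]
C1 XB   0.00

[residue SCP]
N1 XP   1.00

[residue SCN]
O1 XN  -0.50
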