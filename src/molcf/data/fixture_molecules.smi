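# Curated fixture molecules: name after the SMILES is informational only.
CC(=O)O acetic_acid
CCC(=O)O propionic_acid
OC(=O)c1ccccc1 benzoic_acid
OC(=O)CCc1ccccc1 hydrocinnamic_acid
CC(=O)OC methyl_acetate
CC(=O)OCC ethyl_acetate
COC(=O)c1ccccc1 methyl_benzoate
CCO ethanol
CC(C)O isopropanol
OCCO ethylene_glycol
CCN ethylamine
CCNCC diethylamine
c1ccncc1 pyridine
Cc1ccccc1 toluene
c1ccc2ccccc2c1 naphthalene
Cc1ccc(O)cc1 p-cresol
CC(=O)Nc1ccccc1 acetanilide
Clc1ccccc1 chlorobenzene
BrCCBr dibromoethane
FC(F)(F)c1ccccc1 benzotrifluoride
CC(=O)OC1=CC=CC=C1C(=O)O aspirin
CCCCCC hexane
C1CCCCC1 cyclohexane
CSC dimethyl_sulfide
O=S(=O)(O)c1ccccc1 benzenesulfonic_acid
N#Cc1ccccc1 benzonitrile
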