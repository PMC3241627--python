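symbol	name	location	family	urine	blood	fold_change	p_value
APOD	apolipoprotein D	Extracellular space	transporter	•	•	2.803	2.00E-03
C1QTNF3	C1q and tumor necrosis factor related protein 3	Extracellular Space	other	•		1.100	2.50E-02
CD27	CD27 molecule	Plasma Membrane	Transmembrane receptor	•	•	1.183	8.19E-04
CFB	complement factor B	Extracellular Space	peptidase	•		3.231	4.00E-03
CFH	complement factor H	Extracellular Space	other	•	•	1.381	1.00E-03
CLU	clusterin	Extracellular Space	other	•		1.638	1.50E-02
CRABP1	cellular retinoic acid binding protein 1	Cytoplasm	transporter	•		1.477	1.20E-02
DDAH2	dimethylarginine dimethylaminohydrolase 2	Cytoplasm	enzyme	•		1.152	4.80E-02
FTL	ferritin, light polypeptide	Cytoplasm	other	•		1.718	3.00E-03
IGSF8	immunoglobulin superfamily, member 8	Plasma Membrane	other	•	•	1.358	6.00E-03
ITIH4	inter-alpha (globulin) inhibitor H4	Extracellular Space	other	•	•	1.215	2.40E-02
LGALS3	lectin, galactoside-binding, soluble, 3	Extracellular Space	other	•	•	4.121	5.90E-04
LYZ	lysozyme	Extracellular Space	enzyme	•	•	2.093	4.00E-03
MGAT5	hypothetical LOC151162	Cytoplasm	enzyme	•	•	1.112	3.00E-03
PECAM1	platelet/endothelial cell adhesion molecule	Plasma Membrane	other	•	•	2.404	1.01E-04
RBP4	retinol binding protein 4, plasma	Extracellular Space	transporter	•		1.872	2.70E-02
RECK	reversion-inducing-cysteine-rich protein	Plasma Membrane	other	•		2.569	4.60E-02
SELENBP1	selenium binding protein 1	Cytoplasm	other	•		1.327	1.20E-02
SLIT2	slit homolog 2 (Drosophila)	Extracellular Space	other	•		1.848	3.60E-02
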