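pdb_id	site	kinase	modified_residue	warhead	ligand_type
6HHJ	B	AKT1	Cys310	Acrylamide	VI
6HHF	B	AKT1	Cys296	Acrylamide	VI
6HHI	B	AKT1	Cys296	Acrylamide	VI
6HHH	B	AKT1	Cys296	Acrylamide	VI
6HHG	B	AKT1	Cys310	Acrylamide	VI
6S9X	B	AKT1	Cys310	Acrylamide	VI
6S9W	B	AKT1	Cys310	Acrylamide	VI
3ORX	C	PDPK1	Cys148	Sulfhydryl	VI
5O8V	D	MAPK14	Cys251	Acrylamide	VI
5O8U	D	MAPK14	Cys252	α,β-unsaturated Carbonyl	VI
5OO0	I	CDK2	Cys177	Acrylamide	VI
5OSJ	I	CDK2	Cys117	Acrylamide	VI
5ORL	K	AURKA	Cys247	Thiazoline	VI
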