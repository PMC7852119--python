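# Functional-group key for the substructure fingerprint: one bit per pattern,
# bit i set iff pattern i matches at least once. No hashing.
[CX4]	sp3_carbon
[CX3]=[CX3]	alkene
[CX2]#[CX2]	alkyne
a	aromatic_atom
c1ccccc1	benzene_ring
[cX3](:*):*	aromatic_carbon
[nX2]	aromatic_nitrogen_basic
[nX3]	aromatic_nitrogen_pyrrole
[o]	aromatic_oxygen
[s]	aromatic_sulfur
[OX2H]	hydroxyl
[OX2H][CX4]	aliphatic_alcohol
[OX2H]c	phenol_oh
[OX2]([#6])[#6]	ether
[CX3]=[OX1]	carbonyl
[CX3H1]=O	aldehyde
[#6][CX3](=O)[#6]	ketone
[CX3](=O)[OX2H1,OX1-]	carboxylic_acid
[CX3](=O)[OX2][#6]	ester
[CX3](=O)[NX3]	amide
[NX3;H2;!$(NC=O)]	primary_amine
[NX3;H1;!$(NC=O)]([#6])[#6]	secondary_amine
[NX3;H0;!$(NC=O)]([#6])([#6])[#6]	tertiary_amine
[NX2]=[CX3]	imine
[CX2]#[NX1]	nitrile
[NX3](=O)=O	nitro
[NX3][NX3]	hydrazine
[SX2H]	thiol
[SX2]([#6])[#6]	thioether
[SX4](=O)(=O)	sulfonyl
[F]	fluorine
[Cl]	chlorine
[Br]	bromine
[I]	iodine
[#15]	phosphorus
[OX2][OX2]	peroxide
[R]	ring_atom
[R2]	fused_ring_atom
[r3]	three_membered_ring
[r4]	four_membered_ring
[r5]	five_membered_ring
[r6]	six_membered_ring
[r7]	seven_membered_ring
[+,++]	cation
[-,--]	anion
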