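# Compact SMARTS structural key set for native binary fingerprints.
# One "name<TAB>SMARTS" per line; "#" starts a comment.
benzene	c1ccccc1
arom_ring	a1aaaaa1
arom_5ring	a1aaaa1
fused_arom	c1ccc2ccccc2c1
indole	c1ccc2[nH]ccc2c1
pyridine	n1ccccc1
imidazole	c1cnc[nH]1
furan	o1cccc1
thiophene	s1cccc1
ring3	[R]1[R][R]1
ring4	[R]1[R][R][R]1
ring5_aliph	[C;R]1[C;R][C;R][C;R][C;R]1
ring6_aliph	[C;R]1[C;R][C;R][C;R][C;R][C;R]1
spiro_or_fused	[R2]
hydroxyl	[OX2H]
phenol	c[OX2H]
ether	[#6][OX2;!$([OX2H])][#6]
methoxy_arom	co[CH3]
carbonyl	[CX3]=[OX1]
ketone	[#6][CX3](=O)[#6]
aldehyde	[CX3H1]=O
carboxylic_acid	[CX3](=O)[OX2H1]
ester	[CX3](=O)[OX2H0][#6]
amide	[CX3](=O)[NX3]
amine_primary	[NX3;H2;!$(NC=O)][#6]
amine_secondary	[NX3;H1;!$(NC=O)]([#6])[#6]
amine_tertiary	[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]
arom_nitrogen	[n]
nitro	[NX3](=O)=O
nitrile	C#N
azo	N=N
imine	[CX3]=[NX2]
thiol	[SX2H]
thioether	[#6][SX2][#6]
sulfone	[SX4](=O)(=O)
halogen	[F,Cl,Br,I]
chloro	[Cl]
fluoro	[F]
phosphorus	[#15]
quaternary_c	[CX4]([#6])([#6])([#6])[#6]
methyl	[CH3]
long_chain	CCCCCC
alkene	[CX3]=[CX3]
alkyne	C#C
carbon16	[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6].[#6]
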