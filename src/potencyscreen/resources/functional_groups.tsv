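# Functional-group vocabulary for per-class frequency profiling.
# One "name<TAB>SMARTS" per line; "#" starts a comment. Editable: add or
# replace groups to match any perception scheme of interest.
ROH	[CX4][OX2H]
ROR	[#6][OX2;!$([OX2H])][#6]
RCOR	[#6][CX3](=O)[#6]
RCOOR	[CX3](=O)[OX2H0][#6]
RCHO	[CX3H1]=O
RCOOH	[CX3](=O)[OX2H1]
RNH2	[NX3;H2;!$(NC=O)][#6]
R2NH	[NX3;H1;!$(NC=O)]([#6])[#6]
R3N	[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]
RCN	C#N
RNO2	[NX3](=O)=O
RSH	[SX2H]
RSR	[#6][SX2][#6]
RX	[#6][F,Cl,Br,I]
phenol	c[OX2H]
aromatic_N	[n]
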