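[#6][#16X3]=[OX1]	sulfoxide
[NX3][CX3](=[OX1])[OX2]	carbamate
[#16X4]([NX3])(=[OX1])(=[OX1])[#6]	sulfonamide
[#6;R][#6;R]	
[#6;R]=,:[#6;R]	
[NX3][NX2]=[#6]	hydrazone
[OD2]([#6])[#6]	ether
[NX3][CX3](=[OX1])[#6]	amide
[#6][#16X2]	thiol
[CX4H2]	
[CX4H0]	
[CX4][cX3]1[cX3][cX3][cX3][cX3][cX3]1	benzyl
[#6;R][#7;R]	
[CX3]=[CX3]	alkene
[#16X4](=[OX1])(=[OX1])([#6])[OX2]	sulfonate
[#6][F,Cl,Br,I]	haloalkane
[CX4H3]	
[$([CX3]([#6])[#6]),$([CX3H][#6])]=[$([NX2][#6]),$([NX2H])]	imine
[N][C][N]	
[#6][PX3]	phosphine
[C](=C)(=C)	
[NX1]#[CX2]	nitrile
[CX3](=O)[OX2H1]	
[CX3H1](=O)[#6]	aldehyde
[CX2]#[CX2]	alkyne
[NX3][CX3]=[SX1]	thioamide
[#6][CX3](=O)[OX2H0][#6]	ester
[CX4H1]	
[C](=N)	
[CX3]=[OX1]	carbonyl
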