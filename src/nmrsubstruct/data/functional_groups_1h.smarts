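[CX2]#[CX2]	
[CX3]=[P]	
[CX3][CX2]	
[#16X4]([NX3])(=[OX1])(=[OX1])[#6]	
[CX4H3]	
[#6;R][#6;R]	
[#6;R]=[#7;R]	
[CX3](=O)[OX2H1]	
[#6;R]=,:[#6;R]	
[NX3][CX3]=[CX3]	
[NX3][CX3](=[OX1])[#6]	
[CX3](=[OX1])[OX2][CX3](=[OX1])	
[#6;R]=S	
[CX3]=[OX1]	
[CX3H1](=O)[#6]	
[NX3][NX2]=[#6]	
[#16X4](=[OX1])(=[OX1])([#6])[#6]	
[N][C][N]	
[NX1]#[CX2]	
[NX3][CX3](=[OX1])[OX2]	
[#6]1:[#6]:[#7]:[#7]:[#7]:1	
[CX3]=[Se,S]	
[#6][CX3](=O)[OX2H0][#6]	
[CX3]=[CX2]	
[#6;R]=[O;R0]	
[CX4][cX3]1[cX3][cX3][cX3][cX3][cX3]1	
[#6][NX3][NX3]	
[OX2H][#6X3]=[#6]	
[#6;R][#7;R]	
[#6]1[#6][#6][#6][#6][#6]1	
[CX4H4]	
[CX3](=[OX1])[NX3][CX3](=[OX1])	
[CX3]=[CX3]	
[C](=N)	
[#6][PX3]	
[#6][#16X2]	
[CX1-]	
[#6][NX2]=[NX2][#6]	
[#6][CX3](=O)[#6]	
[$([CX3]([#6])[#6]),$([CX3H][#6])]=[$([NX2][#6]),$([NX2H])]	
[cX3]1[cX3][cX3][cX3][cX3][cX3]1	
[#6][OX2H]	
[CX4H2]	
[#6][F,Cl,Br,I]	
[CX3-]	
[CX2]=[OX1]	
[NX3][CX3]=[SX1]	
[CX4H0]	
[#6;R]=[#6;R0]	
[OD2]([#6])[#6]	
[CX3+]	
[CX1]#[NX2]	
[CX4H1]	
[C](=C)(=C)	
[CX3](=[OX1])[F,Cl,Br,I]	
[CX3]=[SX1]	
[#6][#16X3]=[OX1]	
[CX3]=[SX2]	
[#6;R][#8;R]	
[#16X4](=[OX1])(=[OX1])([#6])[OX2]	
[#6;R]=[Se]	
[OX2H][cX3]1[cX3][cX3][cX3][cX3][cX3]1	
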