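group_id	group_smiles	label
a	[*:1]F	F
b	[*:1]Cl	Cl
c	[*:1]Br	Br
d	[*:1]C	CH3
e	[*:1]C(F)(F)F	CF3
f	[*:1]C=C	CHCH2
g	[*:1]C#C	CCH
h	[*:1]C#N	CN
i	[*:1]N=[N+]=[N-]	N3
j	[*:1]N	NH2
k	[*:1]NC(C)=O	NHAc
l	[*:1]O	OH
m	[*:1]OC	OCH3
n	[*:1]OC(F)(F)F	OCF3
o	[*:1]OC(C)=O	OCOCH3
p	[*:1]OC(=O)C(F)(F)F	OCOCF3
q	[*:1]OC(=O)c1ccccc1	OCOPh
r	[*:1]OS(=O)(=O)C(F)(F)F	OTf
s	[*:1]OS(=O)(=O)c1ccc(C)cc1	OTs
t	[*:1]SC(F)(F)F	SCF3
cf2so2ph	[*:1]C(F)(F)S(=O)(=O)c1ccccc1	CF2SO2Ph
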