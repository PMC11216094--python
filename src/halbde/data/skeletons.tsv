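skeleton_id	template_smiles	description
1	O=C1O[I:1]([*:2])c2ccccc21	benziodoxolone: 1,2-benziodoxol-3(1H)-one ring, carboxylate O bound to the halogen(III) center
2	CC1(C)O[I:1]([*:2])c2ccccc21	1,1-dimethylbenziodoxole: gem-dimethyl alkoxide O bound to the halogen(III) center
3	FC(F)(F)C1(O[I:1]([*:2])c2ccccc21)C(F)(F)F	1,1-bis(trifluoromethyl)benziodoxole: gem-bis(CF3) alkoxide O bound to the halogen(III) center
4	[I:1]1([*:2])c2ccccc2-c2ccccc21	dibenzohalole: biphenyl-2,2'-diyl chelating the halogen(III) center through two aryl carbons
5	O=S1(=O)O[I:1]([*:2])c2ccccc21	benziodoxathiole 3,3-dioxide: sulfonate O bound to the halogen(III) center
6	O=C1N[I:1]([*:2])c2ccccc21	benziodazolone: amide N bound to the halogen(III) center (external-test skeleton)
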