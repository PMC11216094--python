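bde_type,y_halogen,slope,intercept
homolytic,Br,0.89,-13.85
homolytic,Cl,0.76,-26.02
heterolytic,Br,0.96,-20.50
heterolytic,Cl,0.92,-29.39
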