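bde_type,skeleton_id,group_label,halogen,dft,le,ml
homolytic,6,F,I,68.3,,72.7
homolytic,6,F,Br,44.1,47,45.2
homolytic,6,F,Cl,26.2,26.1,27.2
homolytic,1,CF2SO2Ph,I,32.6,,38.1
homolytic,1,CF2SO2Ph,Br,10,15.2,13.3
homolytic,1,CF2SO2Ph,Cl,-6.2,-1.2,-4.5
heterolytic,6,F,I,367.4,,375.8
heterolytic,6,F,Br,342.7,332.2,336.8
heterolytic,6,F,Cl,328.8,308.6,329.1
heterolytic,1,CF2SO2Ph,I,79.9,,86.3
heterolytic,1,CF2SO2Ph,Br,57.6,56.2,56.6
heterolytic,1,CF2SO2Ph,Cl,41.7,44.1,48.9
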