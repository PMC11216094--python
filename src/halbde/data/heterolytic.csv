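skeleton_id,halogen,group_id,group_label,bde_kcal_mol,sentinel
1,I,a,F,375.2,
1,Br,a,F,346.9,
1,Cl,a,F,327.5,
2,I,a,F,354.4,
2,Br,a,F,322.1,
2,Cl,a,F,301.1,
3,I,a,F,345.0,
3,Br,a,F,309.7,
3,Cl,a,F,290.0,
4,I,a,F,324.1,
4,Br,a,F,286.4,
4,Cl,a,F,263.3,
5,I,a,F,353.0,
5,Br,a,F,321.5,
5,Cl,a,F,303.1,
1,I,b,Cl,239.5,
1,Br,b,Cl,214.1,
1,Cl,b,Cl,195.2,
2,I,b,Cl,217.7,
2,Br,b,Cl,188.5,
2,Cl,b,Cl,166.9,
3,I,b,Cl,208.4,
3,Br,b,Cl,176.3,
3,Cl,b,Cl,156.5,
4,I,b,Cl,187.6,
4,Br,b,Cl,154.8,
4,Cl,b,Cl,134.6,
5,I,b,Cl,216.4,
5,Br,b,Cl,188.0,
5,Cl,b,Cl,170.2,
1,I,c,Br,212.7,
1,Br,c,Br,188.4,
1,Cl,c,Br,169.0,
2,I,c,Br,190.8,
2,Br,c,Br,163.3,
2,Cl,c,Br,142.0,
3,I,c,Br,181.6,
3,Br,c,Br,151.3,
3,Cl,c,Br,131.9,
4,I,c,Br,160.7,
4,Br,c,Br,130.9,
4,Cl,c,Br,111.9,
5,I,c,Br,189.5,
5,Br,c,Br,162.2,
5,Cl,c,Br,143.8,
1,I,d,CH3,83.8,
1,Br,d,CH3,66.1,
1,Cl,d,CH3,55.6,
2,I,d,CH3,74.0,
2,Br,d,CH3,57.4,
2,Cl,d,CH3,47.9,
3,I,d,CH3,67.9,
3,Br,d,CH3,51.4,
3,Cl,d,CH3,47.8,
4,I,d,CH3,58.6,
4,Br,d,CH3,44.5,
4,Cl,d,CH3,43.0,
5,I,d,CH3,66.2,
5,Br,d,CH3,48.7,
5,Cl,d,CH3,43.4,
1,I,e,CF3,77.5,
1,Br,e,CF3,56.5,
1,Cl,e,CF3,42.1,
2,I,e,CF3,61.7,
2,Br,e,CF3,40.4,
2,Cl,e,CF3,29.3,
3,I,e,CF3,53.7,
3,Br,e,CF3,30.9,
3,Cl,e,CF3,24.2,
4,I,e,CF3,37.8,
4,Br,e,CF3,19.8,
4,Cl,e,CF3,18.9,
5,I,e,CF3,55.2,
5,Br,e,CF3,32.0,
5,Cl,e,CF3,20.9,
1,I,f,CHCH2,71.2,
1,Br,f,CHCH2,54.2,
1,Cl,f,CHCH2,43.9,
2,I,f,CHCH2,60.3,
2,Br,f,CHCH2,44.9,
2,Cl,f,CHCH2,37.7,
3,I,f,CHCH2,54.2,
3,Br,f,CHCH2,38.4,
3,Cl,f,CHCH2,34.9,
4,I,f,CHCH2,44.0,
4,Br,f,CHCH2,28.8,
4,Cl,f,CHCH2,29.3,
5,I,f,CHCH2,53.0,
5,Br,f,CHCH2,35.9,
5,Cl,f,CHCH2,30.7,
1,I,g,CCH,231.7,
1,Br,g,CCH,207.2,
1,Cl,g,CCH,189.8,
2,I,g,CCH,216.5,
2,Br,g,CCH,192.5,
2,Cl,g,CCH,178.7,
3,I,g,CCH,208.7,
3,Br,g,CCH,183.3,
3,Cl,g,CCH,174.1,
4,I,g,CCH,194.4,
4,Br,g,CCH,171.4,
4,Cl,g,CCH,163.5,
5,I,g,CCH,210.1,
5,Br,g,CCH,183.8,
5,Cl,g,CCH,171.0,
1,I,h,CN,254.7,
1,Br,h,CN,227.8,
1,Cl,h,CN,207.7,
2,I,h,CN,235.6,
2,Br,h,CN,206.1,
2,Cl,h,CN,189.3,
3,I,h,CN,226.6,
3,Br,h,CN,194.4,
3,Cl,h,CN,181.2,
4,I,h,CN,207.8,
4,Br,h,CN,177.1,
4,Cl,h,CN,166.7,
5,I,h,CN,231.0,
5,Br,h,CN,200.5,
5,Cl,h,CN,181.2,
1,I,i,N3,159.6,
1,Br,i,N3,134.1,
1,Cl,i,N3,115.4,
2,I,i,N3,139.5,
2,Br,i,N3,111.3,
2,Cl,i,N3,92.2,
3,I,i,N3,130.4,
3,Br,i,N3,99.5,
3,Cl,i,N3,83.4,
4,I,i,N3,111.6,
4,Br,i,N3,81.9,
4,Cl,i,N3,68.2,
5,I,i,N3,136.6,
5,Br,i,N3,107.7,
5,Cl,i,N3,89.5,
1,I,j,NH2,145.5,
1,Br,j,NH2,121.4,
1,Cl,j,NH2,103.8,
2,I,j,NH2,133.0,
2,Br,j,NH2,108.4,
2,Cl,j,NH2,94.0,
3,I,j,NH2,124.9,
3,Br,j,NH2,99.2,
3,Cl,j,NH2,89.9,
4,I,j,NH2,111.7,
4,Br,j,NH2,87.7,
4,Cl,j,NH2,79.7,
5,I,j,NH2,125.5,
5,Br,j,NH2,99.9,
5,Cl,j,NH2,86.9,
1,I,k,NHAc,113.6,
1,Br,k,NHAc,87.8,
1,Cl,k,NHAc,68.3,
2,I,k,NHAc,97.6,
2,Br,k,NHAc,71.5,
2,Cl,k,NHAc,55.2,
3,I,k,NHAc,89.3,
3,Br,k,NHAc,61.4,
3,Cl,k,NHAc,49.0,
4,I,k,NHAc,73.5,
4,Br,k,NHAc,47.9,
4,Cl,k,NHAc,37.6,
5,I,k,NHAc,92.2,
5,Br,k,NHAc,64.2,
5,Cl,k,NHAc,47.2,
1,I,l,OH,244.1,
1,Br,l,OH,217.6,
1,Cl,l,OH,197.1,
2,I,l,OH,227.3,
2,Br,l,OH,199.1,
2,Cl,l,OH,179.6,
3,I,l,OH,218.4,
3,Br,l,OH,187.7,
3,Cl,l,OH,170.9,
4,I,l,OH,200.9,
4,Br,l,OH,170.3,
4,Cl,l,OH,154.0,
5,I,l,OH,222.9,
5,Br,l,OH,193.6,
5,Cl,l,OH,174.0,
1,I,m,OCH3,,dash
1,Br,m,OCH3,,dash
1,Cl,m,OCH3,,dash
2,I,m,OCH3,,dash
2,Br,m,OCH3,,dash
2,Cl,m,OCH3,,dash
3,I,m,OCH3,,dash
3,Br,m,OCH3,,dash
3,Cl,m,OCH3,,dash
4,I,m,OCH3,,dash
4,Br,m,OCH3,,dash
4,Cl,m,OCH3,,dash
5,I,m,OCH3,,dash
5,Br,m,OCH3,,dash
5,Cl,m,OCH3,,dash
1,I,n,OCF3,,dash
1,Br,n,OCF3,,dash
1,Cl,n,OCF3,,dash
2,I,n,OCF3,,dash
2,Br,n,OCF3,,dash
2,Cl,n,OCF3,,dash
3,I,n,OCF3,,dash
3,Br,n,OCF3,,dash
3,Cl,n,OCF3,,dash
4,I,n,OCF3,,dash
4,Br,n,OCF3,,dash
4,Cl,n,OCF3,,dash
5,I,n,OCF3,,dash
5,Br,n,OCF3,,dash
5,Cl,n,OCF3,,dash
1,I,o,OCOCH3,149.1,
1,Br,o,OCOCH3,122.7,
1,Cl,o,OCOCH3,102.9,
2,I,o,OCOCH3,128.7,
2,Br,o,OCOCH3,100.4,
2,Cl,o,OCOCH3,78.1,
3,I,o,OCOCH3,119.6,
3,Br,o,OCOCH3,87.4,
3,Cl,o,OCOCH3,67.7,
4,I,o,OCOCH3,99.4,
4,Br,o,OCOCH3,67.8,
4,Cl,o,OCOCH3,47.0,
5,I,o,OCOCH3,127.0,
5,Br,o,OCOCH3,97.5,
5,Cl,o,OCOCH3,77.2,
1,I,p,OCOCF3,,dash
1,Br,p,OCOCF3,,dash
1,Cl,p,OCOCF3,,dash
2,I,p,OCOCF3,,dash
2,Br,p,OCOCF3,,dash
2,Cl,p,OCOCF3,,dash
3,I,p,OCOCF3,,dash
3,Br,p,OCOCF3,,dash
3,Cl,p,OCOCF3,,dash
4,I,p,OCOCF3,,dash
4,Br,p,OCOCF3,,dash
4,Cl,p,OCOCF3,,dash
5,I,p,OCOCF3,,dash
5,Br,p,OCOCF3,,dash
5,Cl,p,OCOCF3,,dash
1,I,q,OCOPh,,dash
1,Br,q,OCOPh,,dash
1,Cl,q,OCOPh,,dash
2,I,q,OCOPh,,dash
2,Br,q,OCOPh,,dash
2,Cl,q,OCOPh,,dash
3,I,q,OCOPh,,dash
3,Br,q,OCOPh,,dash
3,Cl,q,OCOPh,,dash
4,I,q,OCOPh,,dash
4,Br,q,OCOPh,,dash
4,Cl,q,OCOPh,,dash
5,I,q,OCOPh,,dash
5,Br,q,OCOPh,,dash
5,Cl,q,OCOPh,,dash
1,I,r,OTf,,dash
1,Br,r,OTf,,dash
1,Cl,r,OTf,,dash
2,I,r,OTf,,dash
2,Br,r,OTf,,dash
2,Cl,r,OTf,,dash
3,I,r,OTf,,dash
3,Br,r,OTf,,dash
3,Cl,r,OTf,,dash
4,I,r,OTf,,dash
4,Br,r,OTf,,dash
4,Cl,r,OTf,,dash
5,I,r,OTf,,dash
5,Br,r,OTf,,dash
5,Cl,r,OTf,,dash
1,I,s,OTs,104.8,
1,Br,s,OTs,79.7,
1,Cl,s,OTs,62.4,
2,I,s,OTs,80.2,
2,Br,s,OTs,50.0,
2,Cl,s,OTs,29.1,
3,I,s,OTs,70.9,
3,Br,s,OTs,37.0,
3,Cl,s,OTs,18.5,
4,I,s,OTs,47.8,
4,Br,s,OTs,13.2,
4,Cl,s,OTs,-7.6,
5,I,s,OTs,,slash
5,Br,s,OTs,52.5,
5,Cl,s,OTs,37.9,
1,I,t,SCF3,,dash
1,Br,t,SCF3,,dash
1,Cl,t,SCF3,,dash
2,I,t,SCF3,,dash
2,Br,t,SCF3,,dash
2,Cl,t,SCF3,,dash
3,I,t,SCF3,,dash
3,Br,t,SCF3,,dash
3,Cl,t,SCF3,,dash
4,I,t,SCF3,,dash
4,Br,t,SCF3,,dash
4,Cl,t,SCF3,,dash
5,I,t,SCF3,,dash
5,Br,t,SCF3,,dash
5,Cl,t,SCF3,,dash
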