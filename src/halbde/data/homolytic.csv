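skeleton_id,halogen,group_id,group_label,bde_kcal_mol,sentinel
1,I,a,F,78.6,
1,Br,a,F,50.5,
1,Cl,a,F,30.5,
2,I,a,F,81.9,
2,Br,a,F,56.6,
2,Cl,a,F,35.5,
3,I,a,F,80.8,
3,Br,a,F,54.3,
3,Cl,a,F,33.3,
4,I,a,F,80.6,
4,Br,a,F,61.4,
4,Cl,a,F,29.4,
5,I,a,F,84.0,
5,Br,a,F,62.0,
5,Cl,a,F,42.9,
1,I,b,Cl,55.3,
1,Br,b,Cl,29.4,
1,Cl,b,Cl,10.1,
2,I,b,Cl,58.1,
2,Br,b,Cl,35.6,
2,Cl,b,Cl,14.0,
3,I,b,Cl,57.4,
3,Br,b,Cl,33.1,
3,Cl,b,Cl,12.1,
4,I,b,Cl,57.1,
4,Br,b,Cl,40.9,
4,Cl,b,Cl,10.7,
5,I,b,Cl,60.1,
5,Br,b,Cl,40.3,
5,Cl,b,Cl,21.3,
1,I,c,Br,44.7,
1,Br,c,Br,19.8,
1,Cl,c,Br,0.2,
2,I,c,Br,47.3,
2,Br,c,Br,24.9,
2,Cl,c,Br,4.3,
3,I,c,Br,46.7,
3,Br,c,Br,23.0,
3,Cl,c,Br,2.4,
4,I,c,Br,46.5,
4,Br,c,Br,31.2,
4,Cl,c,Br,2.0,
5,I,c,Br,49.3,
5,Br,c,Br,30.2,
5,Cl,c,Br,11.4,
1,I,d,CH3,33.2,
1,Br,d,CH3,13.4,
1,Cl,d,CH3,-0.3,
2,I,d,CH3,42.4,
2,Br,d,CH3,28.7,
2,Cl,d,CH3,16.5,
3,I,d,CH3,42.8,
3,Br,d,CH3,29.6,
3,Cl,d,CH3,20.0,
4,I,d,CH3,49.1,
4,Br,d,CH3,49.3,
4,Cl,d,CH3,40.0,
5,I,d,CH3,39.9,
5,Br,d,CH3,28.9,
5,Cl,d,CH3,22.2,
1,I,e,CF3,33.5,
1,Br,e,CF3,13.5,
1,Cl,e,CF3,-0.8,
2,I,e,CF3,39.0,
2,Br,e,CF3,24.5,
2,Cl,e,CF3,11.8,
3,I,e,CF3,38.5,
3,Br,e,CF3,23.6,
3,Cl,e,CF3,12.5,
4,I,e,CF3,41.2,
4,Br,e,CF3,39.0,
4,Cl,e,CF3,25.1,
5,I,e,CF3,37.2,
5,Br,e,CF3,24.5,
5,Cl,e,CF3,12.6,
1,I,f,CHCH2,40.4,
1,Br,f,CHCH2,21.4,
1,Cl,f,CHCH2,8.7,
2,I,f,CHCH2,49.6,
2,Br,f,CHCH2,36.5,
2,Cl,f,CHCH2,25.8,
3,I,f,CHCH2,49.6,
3,Br,f,CHCH2,36.8,
3,Cl,f,CHCH2,28.1,
4,I,f,CHCH2,56.0,
4,Br,f,CHCH2,58.2,
4,Cl,f,CHCH2,47.1,
5,I,f,CHCH2,46.8,
5,Br,f,CHCH2,36.1,
5,Cl,f,CHCH2,27.0,
1,I,g,CCH,66.1,
1,Br,g,CCH,42.0,
1,Cl,g,CCH,24.5,
2,I,g,CCH,73.1,
2,Br,g,CCH,53.9,
2,Cl,g,CCH,38.2,
3,I,g,CCH,72.6,
3,Br,g,CCH,53.0,
3,Cl,g,CCH,39.2,
4,I,g,CCH,76.3,
4,Br,g,CCH,68.5,
4,Cl,g,CCH,48.5,
5,I,g,CCH,71.1,
5,Br,g,CCH,53.8,
5,Cl,g,CCH,39.0,
1,I,h,CN,68.8,
1,Br,h,CN,43.6,
1,Cl,h,CN,24.2,
2,I,h,CN,72.6,
2,Br,h,CN,51.6,
2,Cl,h,CN,33.4,
3,I,h,CN,71.6,
3,Br,h,CN,49.7,
3,Cl,h,CN,32.7,
4,I,h,CN,72.8,
4,Br,h,CN,61.6,
4,Cl,h,CN,37.9,
5,I,h,CN,71.9,
5,Br,h,CN,53.0,
5,Cl,h,CN,34.8,
1,I,i,N3,32.1,
1,Br,i,N3,7.6,
1,Cl,i,N3,-11.2,
2,I,i,N3,35.8,
2,Br,i,N3,14.6,
2,Cl,i,N3,-4.5,
3,I,i,N3,34.8,
3,Br,i,N3,12.3,
3,Cl,i,N3,-6.3,
4,I,i,N3,36.3,
4,Br,i,N3,23.3,
4,Cl,i,N3,-4.8,
5,I,i,N3,36.5,
5,Br,i,N3,17.9,
5,Cl,i,N3,0.1,
1,I,j,NH2,37.7,
1,Br,j,NH2,12.6,
1,Cl,j,NH2,-4.3,
2,I,j,NH2,45.5,
2,Br,j,NH2,25.1,
2,Cl,j,NH2,9.6,
3,I,j,NH2,45.0,
3,Br,j,NH2,24.1,
3,Cl,j,NH2,8.3,
4,I,j,NH2,49.4,
4,Br,j,NH2,40.2,
4,Cl,j,NH2,16.7,
5,I,j,NH2,44.5,
5,Br,j,NH2,27.5,
5,Cl,j,NH2,11.7,
1,I,k,NHAc,47.6,
1,Br,k,NHAc,22.0,
1,Cl,k,NHAc,2.6,
2,I,k,NHAc,53.4,
2,Br,k,NHAc,31.6,
2,Cl,k,NHAc,13.0,
3,I,k,NHAc,52.7,
3,Br,k,NHAc,30.0,
3,Cl,k,NHAc,12.2,
4,I,k,NHAc,55.8,
4,Br,k,NHAc,43.4,
4,Cl,k,NHAc,18.8,
5,I,k,NHAc,53.0,
5,Br,k,NHAc,33.7,
5,Cl,k,NHAc,15.7,
1,I,l,OH,53.0,
1,Br,l,OH,26.4,
1,Cl,l,OH,6.5,
2,I,l,OH,58.7,
2,Br,l,OH,35.7,
2,Cl,l,OH,15.9,
3,I,l,OH,57.7,
3,Br,l,OH,33.5,
3,Cl,l,OH,14.1,
4,I,l,OH,60.1,
4,Br,l,OH,44.9,
4,Cl,l,OH,16.3,
5,I,l,OH,58.7,
5,Br,l,OH,38.3,
5,Cl,l,OH,19.5,
1,I,m,OCH3,40.7,
1,Br,m,OCH3,15.3,
1,Cl,m,OCH3,-3.5,
2,I,m,OCH3,46.2,
2,Br,m,OCH3,24.6,
2,Cl,m,OCH3,6.1,
3,I,m,OCH3,45.2,
3,Br,m,OCH3,22.4,
3,Cl,m,OCH3,4.3,
4,I,m,OCH3,47.9,
4,Br,m,OCH3,34.5,
4,Cl,m,OCH3,7.7,
5,I,m,OCH3,46.2,
5,Br,m,OCH3,26.9,
5,Cl,m,OCH3,9.1,
1,I,n,OCF3,62.9,
1,Br,n,OCF3,37.0,
1,Cl,n,OCF3,18.4,
2,I,n,OCF3,64.4,
2,Br,n,OCF3,40.5,
2,Cl,n,OCF3,19.8,
3,I,n,OCF3,63.5,
3,Br,n,OCF3,38.1,
3,Cl,n,OCF3,17.4,
4,I,n,OCF3,62.7,
4,Br,n,OCF3,45.0,
4,Cl,n,OCF3,13.3,
5,I,n,OCF3,67.0,
5,Br,n,OCF3,46.6,
5,Cl,n,OCF3,28.6,
1,I,o,OCOCH3,54.6,
1,Br,o,OCOCH3,27.4,
1,Cl,o,OCOCH3,7.5,
2,I,o,OCOCH3,58.1,
2,Br,o,OCOCH3,33.7,
2,Cl,o,OCOCH3,12.3,
3,I,o,OCOCH3,57.5,
3,Br,o,OCOCH3,31.1,
3,Cl,o,OCOCH3,9.9,
4,I,o,OCOCH3,57.6,
4,Br,o,OCOCH3,39.3,
4,Cl,o,OCOCH3,8.6,
5,I,o,OCOCH3,59.1,
5,Br,o,OCOCH3,37.1,
5,Cl,o,OCOCH3,17.4,
1,I,p,OCOCF3,62.3,
1,Br,p,OCOCF3,36.1,
1,Cl,p,OCOCF3,17.4,
2,I,p,OCOCF3,63.5,
2,Br,p,OCOCF3,39.0,
2,Cl,p,OCOCF3,18.0,
3,I,p,OCOCF3,62.7,
3,Br,p,OCOCF3,36.7,
3,Cl,p,OCOCF3,15.8,
4,I,p,OCOCF3,61.2,
4,Br,p,OCOCF3,43.4,
4,Cl,p,OCOCF3,11.3,
5,I,p,OCOCF3,65.9,
5,Br,p,OCOCF3,45.1,
5,Cl,p,OCOCF3,27.0,
1,I,q,OCOPh,55.8,
1,Br,q,OCOPh,28.5,
1,Cl,q,OCOPh,8.7,
2,I,q,OCOPh,58.9,
2,Br,q,OCOPh,33.8,
2,Cl,q,OCOPh,12.4,
3,I,q,OCOPh,58.4,
3,Br,q,OCOPh,31.8,
3,Cl,q,OCOPh,10.4,
4,I,q,OCOPh,58.4,
4,Br,q,OCOPh,40.5,
4,Cl,q,OCOPh,9.0,
5,I,q,OCOPh,60.1,
5,Br,q,OCOPh,38.0,
5,Cl,q,OCOPh,19.1,
1,I,r,OTf,66.3,
1,Br,r,OTf,41.9,
1,Cl,r,OTf,25.8,
2,I,r,OTf,65.1,
2,Br,r,OTf,41.3,
2,Cl,r,OTf,21.3,
3,I,r,OTf,64.3,
3,Br,r,OTf,39.0,
3,Cl,r,OTf,18.7,
4,I,r,OTf,62.0,
4,Br,r,OTf,43.6,
4,Cl,r,OTf,11.1,
5,I,r,OTf,69.8,
5,Br,r,OTf,50.8,
5,Cl,r,OTf,35.4,
1,I,s,OTs,61.8,
1,Br,s,OTs,36.5,
1,Cl,s,OTs,18.4,
2,I,s,OTs,62.4,
2,Br,s,OTs,38.4,
2,Cl,s,OTs,18.3,
3,I,s,OTs,62.3,
3,Br,s,OTs,36.2,
3,Cl,s,OTs,15.5,
4,I,s,OTs,61.0,
4,Br,s,OTs,43.0,
4,Cl,s,OTs,12.9,
5,I,s,OTs,65.8,
5,Br,s,OTs,45.8,
5,Cl,s,OTs,28.9,
1,I,t,SCF3,40.1,
1,Br,t,SCF3,16.1,
1,Cl,t,SCF3,-3.1,
2,I,t,SCF3,44.6,
2,Br,t,SCF3,23.3,
2,Cl,t,SCF3,4.0,
3,I,t,SCF3,43.2,
3,Br,t,SCF3,21.6,
3,Cl,t,SCF3,3.0,
4,I,t,SCF3,44.9,
4,Br,t,SCF3,33.7,
4,Cl,t,SCF3,14.0,
5,I,t,SCF3,44.2,
5,Br,t,SCF3,26.2,
5,Cl,t,SCF3,7.9,
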