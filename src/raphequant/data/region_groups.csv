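id,name,group,excluded
1,Olf Nuclei,Olfactory,False
2,Claustrum,Cortex,False
3,Anterior Ctx,Cortex,False
4,Motor Ctx,Cortex,False
5,Piriform Ctx,Cortex,False
6,S.S. Ctx,Cortex,False
7,Visual Ctx,Cortex,False
8,Other Ctx,Cortex,False
9,NAcCore,Striatum,False
10,NAcMed,Striatum,False
11,NAcLat,Striatum,False
12,DStr,Striatum,False
13,VP,Pallidum,False
14,GPe,Pallidum,False
15,GPi,Pallidum,False
16,SI,Pallidum,False
17,BNST,Extended Amygdala,False
18,CeM,Extended Amygdala,False
19,CeC,Extended Amygdala,False
20,CeL,Extended Amygdala,False
21,BLA,Extended Amygdala,False
22,DB,Septum,False
23,Septum,Septum,False
24,PVA,Thalamus,False
25,MHb,Thalamus,False
26,LHb,Thalamus,False
27,Other Thal,Thalamus,False
28,PVH,Hypothalamus,False
29,LH,Hypothalamus,False
30,VMH,Hypothalamus,False
31,STh,Hypothalamus,False
32,MMB,Hypothalamus,False
33,PO,Hypothalamus,False
34,ZI,Hypothalamus,False
35,SN,Midbrain,False
36,DpMe,Midbrain,False
37,Sup. Col.,Midbrain,False
38,PAG,Midbrain,False
39,IPN,Midbrain,False
40,MnR,Midbrain,False
41,PPTg,Pons,False
42,LDTg,Pons,False
43,PBN,Pons,False
44,PnR,Pons,False
45,RMg,Pons,False
46,DR,Midbrain,True
47,VTA,Midbrain,True
48,CLi,Midbrain,True
49,RLi,Midbrain,True
50,olfactory bulb,Olfactory,True
51,cerebellum,Hindbrain,True
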