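node_index,aal_name,abbreviation,hemisphere
0,Precentral_L,PreCG.L,L
1,Precentral_R,PreCG.R,R
2,Frontal_Sup_L,SFGdor.L,L
3,Frontal_Sup_R,SFGdor.R,R
4,Frontal_Sup_Orb_L,ORBsup.L,L
5,Frontal_Sup_Orb_R,ORBsup.R,R
6,Frontal_Mid_L,MFG.L,L
7,Frontal_Mid_R,MFG.R,R
8,Frontal_Mid_Orb_L,ORBmid.L,L
9,Frontal_Mid_Orb_R,ORBmid.R,R
10,Frontal_Inf_Oper_L,IFGoperc.L,L
11,Frontal_Inf_Oper_R,IFGoperc.R,R
12,Frontal_Inf_Tri_L,IFGtriang.L,L
13,Frontal_Inf_Tri_R,IFGtriang.R,R
14,Frontal_Inf_Orb_L,ORBinf.L,L
15,Frontal_Inf_Orb_R,ORBinf.R,R
16,Rolandic_Oper_L,ROL.L,L
17,Rolandic_Oper_R,ROL.R,R
18,Supp_Motor_Area_L,SMA.L,L
19,Supp_Motor_Area_R,SMA.R,R
20,Olfactory_L,OLF.L,L
21,Olfactory_R,OLF.R,R
22,Frontal_Sup_Medial_L,SFGmed.L,L
23,Frontal_Sup_Medial_R,SFGmed.R,R
24,Frontal_Med_Orb_L,ORBsupmed.L,L
25,Frontal_Med_Orb_R,ORBsupmed.R,R
26,Rectus_L,REC.L,L
27,Rectus_R,REC.R,R
28,Insula_L,INS.L,L
29,Insula_R,INS.R,R
30,Cingulum_Ant_L,ACG.L,L
31,Cingulum_Ant_R,ACG.R,R
32,Cingulum_Mid_L,DCG.L,L
33,Cingulum_Mid_R,DCG.R,R
34,Cingulum_Post_L,PCG.L,L
35,Cingulum_Post_R,PCG.R,R
36,Hippocampus_L,HIP.L,L
37,Hippocampus_R,HIP.R,R
38,ParaHippocampal_L,PHG.L,L
39,ParaHippocampal_R,PHG.R,R
40,Amygdala_L,AMYG.L,L
41,Amygdala_R,AMYG.R,R
42,Calcarine_L,CAL.L,L
43,Calcarine_R,CAL.R,R
44,Cuneus_L,CUN.L,L
45,Cuneus_R,CUN.R,R
46,Lingual_L,LING.L,L
47,Lingual_R,LING.R,R
48,Occipital_Sup_L,SOG.L,L
49,Occipital_Sup_R,SOG.R,R
50,Occipital_Mid_L,MOG.L,L
51,Occipital_Mid_R,MOG.R,R
52,Occipital_Inf_L,IOG.L,L
53,Occipital_Inf_R,IOG.R,R
54,Fusiform_L,FFG.L,L
55,Fusiform_R,FFG.R,R
56,Postcentral_L,PoCG.L,L
57,Postcentral_R,PoCG.R,R
58,Parietal_Sup_L,SPG.L,L
59,Parietal_Sup_R,SPG.R,R
60,Parietal_Inf_L,IPL.L,L
61,Parietal_Inf_R,IPL.R,R
62,SupraMarginal_L,SMG.L,L
63,SupraMarginal_R,SMG.R,R
64,Angular_L,ANG.L,L
65,Angular_R,ANG.R,R
66,Precuneus_L,PCUN.L,L
67,Precuneus_R,PCUN.R,R
68,Paracentral_Lobule_L,PCL.L,L
69,Paracentral_Lobule_R,PCL.R,R
70,Caudate_L,CAU.L,L
71,Caudate_R,CAU.R,R
72,Putamen_L,PUT.L,L
73,Putamen_R,PUT.R,R
74,Pallidum_L,PAL.L,L
75,Pallidum_R,PAL.R,R
76,Thalamus_L,THA.L,L
77,Thalamus_R,THA.R,R
78,Heschl_L,HES.L,L
79,Heschl_R,HES.R,R
80,Temporal_Sup_L,STG.L,L
81,Temporal_Sup_R,STG.R,R
82,Temporal_Pole_Sup_L,TPOsup.L,L
83,Temporal_Pole_Sup_R,TPOsup.R,R
84,Temporal_Mid_L,MTG.L,L
85,Temporal_Mid_R,MTG.R,R
86,Temporal_Pole_Mid_L,TPOmid.L,L
87,Temporal_Pole_Mid_R,TPOmid.R,R
88,Temporal_Inf_L,ITG.L,L
89,Temporal_Inf_R,ITG.R,R
90,Cerebellum_Crus1_L,CRBLCrus1.L,L
91,Cerebellum_Crus1_R,CRBLCrus1.R,R
92,Cerebellum_Crus2_L,CRBLCrus2.L,L
93,Cerebellum_Crus2_R,CRBLCrus2.R,R
94,Cerebellum_3_L,CRBL3.L,L
95,Cerebellum_3_R,CRBL3.R,R
96,Cerebellum_4_5_L,CRBL45.L,L
97,Cerebellum_4_5_R,CRBL45.R,R
98,Cerebellum_6_L,CRBL6.L,L
99,Cerebellum_6_R,CRBL6.R,R
100,Cerebellum_7b_L,CRBL7b.L,L
101,Cerebellum_7b_R,CRBL7b.R,R
102,Cerebellum_8_L,CRBL8.L,L
103,Cerebellum_8_R,CRBL8.R,R
104,Cerebellum_9_L,CRBL9.L,L
105,Cerebellum_9_R,CRBL9.R,R
106,Cerebellum_10_L,CRBL10.L,L
107,Cerebellum_10_R,CRBL10.R,R
108,Vermis_1_2,Vermis12,vermis
109,Vermis_3,Vermis3,vermis
110,Vermis_4_5,Vermis45,vermis
111,Vermis_6,Vermis6,vermis
112,Vermis_7,Vermis7,vermis
113,Vermis_8,Vermis8,vermis
114,Vermis_9,Vermis9,vermis
115,Vermis_10,Vermis10,vermis
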