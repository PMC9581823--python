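region_id,name,cortical,network
1,Precentral_L,true,OTHER_CORTICAL
2,Precentral_R,true,OTHER_CORTICAL
3,Frontal_Sup_L,true,OTHER_CORTICAL
4,Frontal_Sup_R,true,OTHER_CORTICAL
5,Frontal_Sup_Orb_L,true,OTHER_CORTICAL
6,Frontal_Sup_Orb_R,true,OTHER_CORTICAL
7,Frontal_Mid_L,true,FPN
8,Frontal_Mid_R,true,FPN
9,Frontal_Mid_Orb_L,true,OTHER_CORTICAL
10,Frontal_Mid_Orb_R,true,OTHER_CORTICAL
11,Frontal_Inf_Oper_L,true,OTHER_CORTICAL
12,Frontal_Inf_Oper_R,true,OTHER_CORTICAL
13,Frontal_Inf_Tri_L,true,FPN
14,Frontal_Inf_Tri_R,true,FPN
15,Frontal_Inf_Orb_L,true,OTHER_CORTICAL
16,Frontal_Inf_Orb_R,true,OTHER_CORTICAL
17,Rolandic_Oper_L,true,OTHER_CORTICAL
18,Rolandic_Oper_R,true,OTHER_CORTICAL
19,Supp_Motor_Area_L,true,OTHER_CORTICAL
20,Supp_Motor_Area_R,true,OTHER_CORTICAL
21,Olfactory_L,true,OTHER_CORTICAL
22,Olfactory_R,true,OTHER_CORTICAL
23,Frontal_Sup_Medial_L,true,DMN
24,Frontal_Sup_Medial_R,true,DMN
25,Frontal_Med_Orb_L,true,DMN
26,Frontal_Med_Orb_R,true,DMN
27,Rectus_L,true,OTHER_CORTICAL
28,Rectus_R,true,OTHER_CORTICAL
29,Insula_L,true,OTHER_CORTICAL
30,Insula_R,true,OTHER_CORTICAL
31,Cingulum_Ant_L,true,DMN
32,Cingulum_Ant_R,true,DMN
33,Cingulum_Mid_L,true,OTHER_CORTICAL
34,Cingulum_Mid_R,true,OTHER_CORTICAL
35,Cingulum_Post_L,true,DMN
36,Cingulum_Post_R,true,DMN
37,Hippocampus_L,false,SUBCORTICAL
38,Hippocampus_R,false,SUBCORTICAL
39,ParaHippocampal_L,true,OTHER_CORTICAL
40,ParaHippocampal_R,true,OTHER_CORTICAL
41,Amygdala_L,false,SUBCORTICAL
42,Amygdala_R,false,SUBCORTICAL
43,Calcarine_L,true,OTHER_CORTICAL
44,Calcarine_R,true,OTHER_CORTICAL
45,Cuneus_L,true,OTHER_CORTICAL
46,Cuneus_R,true,OTHER_CORTICAL
47,Lingual_L,true,OTHER_CORTICAL
48,Lingual_R,true,OTHER_CORTICAL
49,Occipital_Sup_L,true,OTHER_CORTICAL
50,Occipital_Sup_R,true,OTHER_CORTICAL
51,Occipital_Mid_L,true,OTHER_CORTICAL
52,Occipital_Mid_R,true,OTHER_CORTICAL
53,Occipital_Inf_L,true,OTHER_CORTICAL
54,Occipital_Inf_R,true,OTHER_CORTICAL
55,Fusiform_L,true,OTHER_CORTICAL
56,Fusiform_R,true,OTHER_CORTICAL
57,Postcentral_L,true,OTHER_CORTICAL
58,Postcentral_R,true,OTHER_CORTICAL
59,Parietal_Sup_L,true,OTHER_CORTICAL
60,Parietal_Sup_R,true,OTHER_CORTICAL
61,Parietal_Inf_L,true,FPN
62,Parietal_Inf_R,true,FPN
63,SupraMarginal_L,true,OTHER_CORTICAL
64,SupraMarginal_R,true,OTHER_CORTICAL
65,Angular_L,true,DMN
66,Angular_R,true,DMN
67,Precuneus_L,true,DMN
68,Precuneus_R,true,DMN
69,Paracentral_Lobule_L,true,OTHER_CORTICAL
70,Paracentral_Lobule_R,true,OTHER_CORTICAL
71,Caudate_L,false,SUBCORTICAL
72,Caudate_R,false,SUBCORTICAL
73,Putamen_L,false,SUBCORTICAL
74,Putamen_R,false,SUBCORTICAL
75,Pallidum_L,false,SUBCORTICAL
76,Pallidum_R,false,SUBCORTICAL
77,Thalamus_L,false,SUBCORTICAL
78,Thalamus_R,false,SUBCORTICAL
79,Heschl_L,true,OTHER_CORTICAL
80,Heschl_R,true,OTHER_CORTICAL
81,Temporal_Sup_L,true,OTHER_CORTICAL
82,Temporal_Sup_R,true,OTHER_CORTICAL
83,Temporal_Pole_Sup_L,true,OTHER_CORTICAL
84,Temporal_Pole_Sup_R,true,OTHER_CORTICAL
85,Temporal_Mid_L,true,DMN
86,Temporal_Mid_R,true,DMN
87,Temporal_Pole_Mid_L,true,OTHER_CORTICAL
88,Temporal_Pole_Mid_R,true,OTHER_CORTICAL
89,Temporal_Inf_L,true,OTHER_CORTICAL
90,Temporal_Inf_R,true,OTHER_CORTICAL
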