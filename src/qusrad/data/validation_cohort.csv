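id,age,er,pr,her2,histology,grade,pre_nac_size_cm,pre_t_stage,pre_n_stage,treatment,treatment_changed,post_nac_size_cm,cellularity_pct,rcb,actual_response,predicted_response
1,47,+,-,-,IDC,III,3,2,1,"AC-Paclitaxel (DD), 8 cycles",False,2.7,50,2.24,NR,NR
2,37,+,+,-,IDC,II-III,4.4,3,0,"FEC100 x3, then Doce100x3",False,2.5,11.25,2.92,R,R
3,47,+,+,-,IDC,III,6.7,2,1,"AC-Paclitaxel (DD), 8 cycles",False,3,3,2.51,R,R
4,50,+,-,-,IDC,III,1.9,1,0,"AC-Paclitaxel (DD), 8 cycles",False,1.3,75,1.98,R,NR
5,42,+,-,-,IDC,III,8.5,3,1,"AC-Paclitaxel (DD), 8 cycles",False,0,0,0,R,R
6,50,+,+,-,IDC,I-II,6.1,2,1,"FEC100 x3, then Doce100 + Tras x3",False,5.28,13.3,3.51,R,R
7,35,+,+,+,IDC,II,8,1,1,"AC x4, then Paclitaxel (DD) + Tras x4",False,5.7,0.2,0.92,R,R
8,67,-,-,+,IDC,II,4,3,1,"FEC100 x3, then Doce100 + Tras x3",False,0,15,0,R,R
9,60,+,-,-,IDC,II,2.4,3,3,"FEC100 x3, then Doce100x3",False,7.2,5,2.72,R,R
10,45,-,-,-,IDC,III,2.7,3,1,"AC x4, then Paclitaxel (DD) + Tras x4",False,2.5,3,1.27,R,R
11,50,+,+,+,IDC,II,10.7,2,1,"AC x4, then Paclitaxel (DD) + Tras x4",False,2.4,9,3.24,R,R
12,51,+,+,-,IDC,III,4,2,1,"FEC100 x3, then Doce100x3",False,2,5,2.36,R,NR
13,40,+,+,+,IDC,II,5.9,3,1,"FEC100 x3, then Doce100x3",False,6,0,0,R,R
14,72,+,+,+,IDC,III,3.5,1,1,"FEC100 x3, then Doce100 + Tras x3",False,1.2,0,0,R,R
15,63,-,-,-,IDC,III,4,2,1,"AC-Paclitaxel (DD), 8 cycles",False,0.5,40,1.58,R,R
16,56,+,-,-,IDC,III,3.5,4,1,"Docetaxel-cyclophosphamide, 4 cycles",False,1.9,80,3.09,R,R
17,49,+,+,+,IDC,II,4.9,2,0,"FEC100 x3, then Doce100 + Tras x3",False,2.5,10,1.59,R,R
18,50,+,+,-,IDC,I,3,2,1,"AC-Paclitaxel (DD), 8 cycles",False,3.2,10,3.09,R,NR
19,60,-,-,-,IDC,II,7.3,2,1,"AC-Paclitaxel (DD), 8 cycles",True,4,10,3.01,NR,R
20,41,+,-,-,IDC,II-III,7.5,3,0,"AC-Paclitaxel (DD), 8 cycles",False,2,0,0,R,R
21,72,-,-,-,IMC,III,4.7,2,0,"AC-Paclitaxel (DD), 8 cycles",True,3.5,NA,NA,NR,NR
22,53,-,-,-,IDC,III,3.1,3,0,"AC-Paclitaxel (DD), 8 cycles",False,1.5,0,0,R,R
23,63,+,+,-,IDC,II,7.4,2,2,"FEC100 x3, then Doce100x3",False,7.5,15,3.82,R,R
24,64,+,+,+,IDC,I-II,3.4,2,0,"FEC100 x3, then Doce100 + Tras x3",False,1.7,5,NA,R,R
25,71,+,-,-,IDC,III,1.7,2,0,"Weekly Paclitaxel x12+Tras x4",False,0,0,0,R,R
26,43,-,-,-,IDC,II-III,5.6,2,0,"AC-Paclitaxel (DD), 8 cycles",False,1.8,1,0.37,R,R
27,80,-,-,-,IDC,III,10,2,1,"AC x4, then weekly paclitaxel x12",False,4,10,3.20,R,R
28,37,+,+,-,ILC,I-II,12,3,1,"FEC100 x3, then Doce100x3",False,8,15,3.62,R,R
29,27,-,-,-,IDC,II-III,1.8,1,0,"AC-Paclitaxel, DD, 8 cycles",False,1.5,10,1.29,R,R
30,37,+,+,+,IDC,II,2.6,2,0,"FEC100 x3, then Doce100x3",False,2.5,10,2.35,R,R
31,60,-,-,-,IDC,III,3.2,3,1,"AC-Paclitaxel (DD), 8 cycles",False,2.5,30,1.94,R,R
32,72,+,+,-,IDC,I,3.4,2,0,"AC-Paclitaxel (DD), 8 cycles",False,1.5,30,2.87,R,R
33,45,+,+,-,IDC,III,9.5,2,1,"AC x4, then weekly paclitaxel x12",False,4,25,1.99,R,R
34,43,-,-,-,IDC,III,2.1,2,0,"AC-Paclitaxel (DD), 8 cycles",False,0.2,10,0.95,R,R
35,53,-,-,+,IDC,III,2.5,2,1,"AC x4, then Paclitaxel (DD) + Tras x4",False,2.5,3.66,0.92,R,R
36,54,+,-,+,IDC,II,3.5,2,0,"FEC100 x3, then Doce100 + Tras x3",False,0,0,pCR,R,R
37,48,+,-,+,IDC,III,7.5,1,1,"FEC100 x3, then Doce100 + Tras x3",False,0.65,5,2.41,R,R
38,68,+,-,-,IDC,III,3.6,2,1,"AC-Paclitaxel (DD), 8 cycles",False,4,40,3.83,R,R
39,51,+,+,-,IDC,II,11,3,1,"FEC100 x3, then Doce100x3",False,8.85,6.5,3.56,R,R
40,73,+,+,-,IDC,III,7.8,3,2,"AC-Paclitaxel (DD), 8 cycles",False,4.5,1,1.2,R,R
41,61,-,-,+,IDC,III,2.9,2,0,"FEC100 x3, then Doce100 + Tras x3",False,1.4,10,1.33,R,R
42,44,+,-,-,IDC,III,6.4,2,0,"AC-Paclitaxel (DD), 8 cycles",False,4,0,pCR,R,R
43,29,+,+,-,IDC,III,8.3,3,1,"AC-Paclitaxel (DD), 8 cycles",False,8,2,2.72,R,R
44,65,-,-,-,IDC,II,2.3,2,0,"AC-Paclitaxel (DD), 8 cycles",False,0.9,15,1.43,R,R
45,43,-,-,-,IDC,III,2.4,4,0,"AC (DD) x4, then weekly paclitaxel x12",False,2,0,0,R,R
46,32,+,+,+,IDC,II,7.5,3,1,"AC (DD) x4, then weekly paclitaxel x12 + Tras x 4",False,6.6,5.5,3.48,R,R
47,68,+,+,-,IDC,II,5,4,1,"AC-Paclitaxel (DD), 8 cycles",False,2,12.5,1.60,R,R
48,41,+,+,-,IDC,II,2.9,1,1,"AC-Paclitaxel (DD), 8 cycles",False,2.8,25,3.07,R,R
49,34,-,-,-,IDC,III,1.9,1,1,"Docetaxel-cyclophosphamide, 4 cycles",False,1.3,0,pCR,R,R
50,51,-,-,-,IDC,III,1.9,1,1,"AC-Paclitaxel (DD), 8 cycles",False,2.5,70,3.88,NR,NR
51,42,-,-,+,IDC,III,3.6,2,1,"AC (DD) x4, then weekly paclitaxel x12 + Tras x 4",False,3.5,1,0.78,R,R
52,51,+,+,-,IDC,III,3.3,2,0,"AC-Paclitaxel (DD), 8 cycles",False,5.5,0.05,0.72,R,R
53,31,+,+,+,IDC,III,2.6,2,1,"AC (DD) x4, then weekly paclitaxel x12 + Tras x 4",True,7.86,1.72,1.12,NR,R
54,44,-,-,+,IDC,III,3.7,2,0,"FEC100 x3, then Doce100 + Tras x3",False,0,0,pCR,R,R
55,47,+,+,-,IDC,III,4.8,2,1,"AC-Paclitaxel (DD), 8 cycles",False,2,75,3.85,R,R
56,34,+,+,-,IDC,II,3.2,2,1,"AC-Paclitaxel (DD), 8 cycles",False,6.5,15,3.12,NR,NR
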