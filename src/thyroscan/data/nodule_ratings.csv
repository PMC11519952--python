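nodule,patient,rater,size_mm,composition,echogenicity,margin,shape,foci,recommendation
1,1,robot,3.9,2,2,0,3,0,no FNA
1,1,clinician,3.2,2,2,0,3,0,no FNA
2,2,robot,3.0,2,2,0,0,0,no FNA
2,2,clinician,4.5,1,1,0,0,0,no FNA
3,3,robot,6.6,0,0,0,0,0,no FNA
3,3,clinician,6.9,0,0,0,0,0,no FNA
4,3,robot,5.9,2,1,0,0,0,no FNA
4,3,clinician,6.1,1,1,0,0,0,no FNA
5,4,robot,12.4,2,2,0,0,0,follow-up
5,4,clinician,12.8,2,1,0,0,0,no FNA
6,5,robot,4.2,2,2,0,0,0,no FNA
6,5,clinician,3.4,0,0,0,0,0,no FNA
7,5,robot,6.9,2,1,0,0,0,no FNA
7,5,clinician,6.9,1,2,0,0,0,no FNA
8,6,robot,6.2,1,2,0,0,0,no FNA
8,6,clinician,5.5,1,1,0,0,0,no FNA
9,7,robot,6.7,1,2,0,0,0,no FNA
9,7,clinician,7.8,1,2,0,0,0,no FNA
10,7,robot,7.3,2,2,0,0,0,no FNA
10,7,clinician,7.2,1,2,0,0,0,no FNA
11,7,robot,6.6,2,2,0,0,0,no FNA
11,7,clinician,6.2,1,1,0,0,0,no FNA
12,7,robot,1.8,2,2,0,0,0,no FNA
12,7,clinician,2.4,1,1,0,0,0,no FNA
13,7,robot,3.1,2,2,0,0,0,no FNA
13,7,clinician,2.8,1,1,0,0,0,no FNA
14,8,robot,7.8,1,2,0,0,0,no FNA
14,8,clinician,7.6,1,1,0,0,0,no FNA
15,8,robot,4.3,1,1,0,0,0,no FNA
15,8,clinician,4.4,1,1,0,0,0,no FNA
16,8,robot,7.1,1,1,0,0,0,no FNA
16,8,clinician,7.5,1,1,0,0,0,no FNA
17,8,robot,1.7,1,1,0,0,0,no FNA
17,8,clinician,1.9,1,1,0,0,0,no FNA
18,8,robot,3.1,1,1,0,0,0,no FNA
18,8,clinician,4.1,1,1,0,0,0,no FNA
19,9,robot,18.6,1,2,0,0,0,follow-up
19,9,clinician,19.1,1,2,0,0,0,follow-up
20,9,robot,10.4,1,2,0,0,2,FNA
20,9,clinician,10.6,1,2,0,0,2,FNA
21,10,robot,5.8,1,2,0,0,0,no FNA
21,10,clinician,8.2,1,1,0,0,0,no FNA
22,11,robot,3.0,1,2,0,0,0,no FNA
22,11,clinician,3.6,1,1,0,0,0,no FNA
23,12,robot,17.0,2,1,0,0,0,no FNA
23,12,clinician,18.2,2,1,0,0,0,no FNA
24,13,robot,8.9,2,1,0,0,0,no FNA
24,13,clinician,9.7,1,1,0,0,0,no FNA
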