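patient,fc,interictal_eeg,ictal_eeg,resection_side,cva_mri,cva_pet,q_volume,q_flair,q_pet,seeg,hs_type,outcome,follow_up_months
1,YES,Non-lat,RT > LT,R,n,w,p,p,p,Yes,2,1a,30
2,NO,LT,LFT,L,n,p,n,n,p,Yes,3,1a,27
3,NO,LFT,LT,L,n,n,w,w,n,Yes,3,1a,27
4,YES,Non-lat,Non-lat,L,p,p,p,w,p,Yes,2,1a,21
5,NO,LFT,LT,L,p,p,p,p,p,Yes,1,1a,19
6,YES,LT,LF,L,n,n,p,p,p,Yes,3,1a,18
7,NO,LT,Non-lat,L,p,p,p,p,p,Yes,1,1b,28
8,NO,RFT,RT,R,p,p,p,p,p,No,2,1d,30
9,NO,LFT,LH,L,n,p,w,n,p,Yes,2,1a,34
10,NO,LT,LH,L,p,n,p,p,p,No,2,1a,25
11,NO,LT,LT,L,p,p,p,p,p,No,1,1b,24
12,YES,RT,RT,R,p,p,p,p,p,No,2,1a,17
13,NO,LH>RH,LT,L,n,n,p,n,p,No,2,1a,17
14,NO,LT,LFT,L,n,p,p,p,p,Yes,2,1a,17
15,YES,Non-lat,RT,R,p,n,p,p,p,No,1,1a,25
16,YES,LFT > RFT,LT,L,p,p,p,p,p,No,1,1a,18
17,NO,RT,RFT,R,p,p,p,n,p,Yes,1,1a,34
18,YES,RT,RFT,R,p,p,p,n,p,No,1,1a,20
19,NO,RT > LT,RFT,R,p,p,p,n,p,No,1,1d,29
20,NO,LFT,LFT,L,p,p,p,p,p,Yes,2,1a,23
21,YES,LFT,LT,L,p,n,p,n,p,Yes,1,1a,15
22,NO,Non-lat,LH,L,n,n,w,n,p,Yes,2,1a,25
23,NO,Non-lat,LT,L,p,p,p,p,p,No,2,1a,26
24,NO,LT,LT,L,p,p,p,w,p,No,1,1a,20
25,YES,Non-lat,RT,R,p,p,p,p,p,No,3,1d,23
26,YES,LT,LT,L,p,p,p,n,p,No,1,1a,20
27,NO,LFT,LT,L,p,p,p,w,p,No,1,1a,28
28,YES,Non-lat,LT,L,p,p,p,n,p,No,2,1a,22
29,YES,LFT,LFT,L,p,p,p,n,p,No,2,1a,19
30,NO,RT,RT,R,p,p,p,p,p,No,1,1a,15
31,NO,LFT,LFT,L,p,p,p,w,p,No,1,1d,27
32,YES,LFT,LT,L,p,p,p,n,p,No,1,1a,31
33,YES,Non-lat,Non-lat,R,n,n,p,p,p,Yes,2,1a,13
34,NO,Non-lat,Non-lat,R,p,p,p,n,p,No,1,1a,12
35,NO,LT,LT>RT,L,p,p,p,w,p,No,1,1a,12
36,NO,RFT > LFT,RFT,R,p,n,p,p,p,No,1,1a,13
37,YES,Non-lat,RFT,R,p,p,p,p,p,No,1,1a,13
38,NO,LT,LT,L,p,p,p,n,p,No,1,1a,12
39,YES,LFT,LFT,L,p,p,p,w,p,No,1,1a,35
40,YES,LFT,LH,L,p,p,p,n,p,No,1,1d,15
41,YES,Non,Non,L,p,p,p,w,p,Yes,1,1b,13
42,YES,LT,LFT,L,p,p,p,n,p,No,1,1a,17
43,YES,LFT,LFT,L,n,p,p,w,p,No,2,1b,13
44,YES,RT,RT,R,p,p,p,p,p,No,1,1a,12
45,YES,RFT > LFT,RH>LH,R,n,p,p,w,p,Yes,2,1a,17
46,NO,LT,LT,L,p,p,p,w,p,No,1,1a,8
47,NO,LT,LT,L,p,p,p,w,p,No,1,1a,15
48,YES,LT,LFT,L,p,p,p,n,p,Yes,1,1a,13
49,YES,RT,RF,R,p,p,p,n,p,Yes,1,1d,16
50,NO,LFT,LFT,L,p,p,p,n,p,No,1,1b,14
51,NO,LT,LT,L,p,p,p,p,p,No,1,1a,17
52,YES,LFT,LH,L,p,p,p,n,p,No,2,1a,8
53,YES,RFT,RT,R,p,p,p,p,p,Yes,1,1a,12
54,NO,RT,RH,R,p,p,p,n,p,Yes,1,1a,14
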