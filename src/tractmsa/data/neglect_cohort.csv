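patient,sex,age,onset_days,etiology,visual_field,line_bisection_pct,bells_left_right,letter_left_right
1,M,59,452,Ischemic,Left extinction,+3.8,14/15,28/29
2,M,43,81,Ischemic,Left extinction,+18.2,11/10,-
3,F,62,227,Ischemic,Normal,-5.6,8/11,19/29
4,M,55,95,Ischemic,Left extinction,+2.72,12/11,29/29
5,M,61,83,Ischemic,Left extinction,-4.8,14/11,29/21
6,F,35,118,Hemorrhagic,Normal,-0.4,15/15,21/23
7,M,53,64,Ischemic,Normal,-,15/15,-
8,M,57,82,Ischemic,Normal,-1.8,15/10,29/30
9,M,41,308,Hemorrhagic,Left hemianopia,+10.4,11/13,30/30
10,M,37,142,Hemorrhagic,Left hemianopia,+63.6,-,-
11,M,46,209,Ischemic,Normal,+1,15/15,-
12,F,68,208,Ischemic,Normal,-,15/15,-
13,F,66,207,Ischemic,Left extinction,+8.2,7/14,6/24
14,M,66,137,Ischemic,Normal,-6,12/15,27/28
15,M,66,74,Hemorrhagic,Normal,+4.7,15/13,-
16,M,58,187,Hemorrhagic,Normal,+0.8,14/13,20/24
17,F,60,103,Hemorrhagic,Left hemianopia,+7.9,14/15,25/29
18,M,57,228,Hemorrhagic,Left hemianopia,+19.5,3/13,17/27
19,F,62,194,Hemorrhagic,Left extinction,+2.8,12/15,10/30
20,F,49,150,Hemorrhagic,Left hemianopia,+38.2,0/13,6/29
21,M,44,"1,434",Ischemic,Left hemianopia,+20,12/13,27/27
22,M,56,202,Ischemic,Left extinction,+6.1,14/13,30/30
23,M,66,151,Ischemic,Left extinction,-7.4,13/13,29/30
24,F,79,98,Ischemic,Normal,+3.9,11/12,30/27
25,M,53,78,Ischemic,Normal,+0.4,14/14,28/30
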