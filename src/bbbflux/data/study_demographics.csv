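subject_id,age,sex,gcs,pupils,multitrauma,ais_head,ais_nonhead,iss,marshall,rotterdam,stockholm,progression,gos
1,55,M,8,1,0,5,1,26,VI,5,3.7,0,4
2,53,F,5,2,0,5,1,25,VI,6,3.6,1,3
4,22,M,7,1,1,4,3,29,VI,6,3.3,0,3
5,23,M,8,0,0,4,0,16,III,4,1.5,0,5
6,20,M,8,2,1,3,2,17,II,3,1.8,1,5
7,38,M,7,0,1,5,3,38,II,3,3.5,0,3
8,25,M,8,0,0,5,0,25,IV,5,2,0,5
9,42,M,3,1,1,5,3,38,II,3,1.5,1,3
10,52,F,3,2,1,4,4,29,III,4,3.5,0,3
11,59,M,7,1,0,5,0,25,VI,4,4.9,0,3
12,62,M,3,0,0,5,0,25,II,3,2,1,1
13,49,M,3,0,0,4,0,16,II,3,1.5,0,5
14,20,M,7,0,0,5,0,25,VI,3,2.5,0,4
15,36,M,7,0,1,4,3,26,III,4,2.8,0,4
16,60,F,4,0,0,5,1,25,VI,4,2.5,0,4
17,48,M,4,2,0,5,0,25,VI,5,3.8,1,1
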