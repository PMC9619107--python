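person,A1,A2,A3,B1,B2,B3,X
1,0,0,0,0,0,0,1
2,0,0,0,0,0,0,2
3,0,0,0,0,0,0,3
4,0,0,0,0,0,0,4
5,0,0,0,0,1,0,5
6,0,0,1,0,0,1,6
7,0,0,0,0,0,0,6
8,0,0,0,0,0,0,6
9,0,0,1,0,0,0,6
10,0,0,0,0,0,0,10
11,0,0,0,0,0,0,11
12,0,0,1,0,1,1,12
13,0,0,0,0,0,0,13
14,0,1,0,0,0,0,14
15,0,0,1,1,2,2,15
16,1,0,0,1,0,0,16
17,1,1,0,1,0,0,17
18,1,1,1,2,1,1,18
19,1,1,0,3,3,3,19
20,1,1,0,4,4,4,20
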