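id,kind,x_m,y_m
1,hand,1.05,1.00
2,hand,1.95,1.62
3,hand,0.95,2.42
4,hand,2.05,3.10
5,hand,1.10,3.94
6,hand,1.90,4.58
7,hand,1.00,5.44
8,hand,2.10,6.16
9,hand,1.15,6.76
10,hand,1.85,7.64
11,hand,0.95,8.34
12,hand,2.00,9.12
13,hand,1.10,9.78
14,hand,1.95,10.60
15,hand,1.05,11.34
16,hand,2.05,11.96
17,hand,1.00,12.80
18,hand,1.90,13.48
19,hand,1.10,14.36
20,hand,1.50,15.00
1,foot,1.30,0.15
2,foot,1.75,0.45
3,foot,1.20,0.90
4,foot,1.85,1.55
5,foot,1.30,2.20
6,foot,1.80,2.95
7,foot,1.25,3.70
8,foot,1.80,4.50
9,foot,1.35,5.30
10,foot,1.75,6.15
11,foot,1.30,7.00
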