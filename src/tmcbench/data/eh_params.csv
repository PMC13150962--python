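Z,symbol,shell,ionization_energy_ev,slater_exponent
1,H,1s,-13.6,1.3
2,He,1s,-5.81,1.7
3,Li,2s,-5.4,0.65
3,Li,2p,-3.5,0.65
4,Be,2s,-10.0,0.975
4,Be,2p,-6.0,0.975
5,B,2s,-15.2,1.3
5,B,2p,-8.5,1.3
6,C,2s,-21.4,1.625
6,C,2p,-11.4,1.625
7,N,2s,-26.0,1.95
7,N,2p,-13.4,1.95
8,O,2s,-32.3,2.275
8,O,2p,-14.8,2.275
9,F,2s,-40.0,2.425
9,F,2p,-18.1,2.425
10,Ne,2s,-5.81,3.1
10,Ne,2p,-3.08,3.1
11,Na,3s,-5.1,0.733
11,Na,3p,-3.0,0.733
12,Mg,3s,-9.0,1.1
12,Mg,3p,-4.5,1.1
13,Al,3s,-12.3,1.167
13,Al,3p,-6.5,1.167
14,Si,3s,-17.3,1.383
14,Si,3p,-9.2,1.383
15,P,3s,-18.6,1.6
15,P,3p,-14.0,1.6
16,S,3s,-20.0,1.817
16,S,3p,-13.3,1.817
17,Cl,3s,-30.0,2.033
17,Cl,3p,-15.0,2.033
18,Ar,3s,-5.81,2.3667
18,Ar,3p,-3.08,2.3667
19,K,4s,-4.34,0.874
19,K,4p,-2.73,0.874
20,Ca,4s,-7.0,1.2
20,Ca,4p,-4.0,1.2
21,Sc,3d,-8.51,2.4
21,Sc,4s,-8.87,1.3
21,Sc,4p,-2.75,1.3
22,Ti,3d,-10.81,2.55
22,Ti,4s,-8.97,1.4
22,Ti,4p,-5.44,1.4
23,V,3d,-11.0,2.7
23,V,4s,-8.81,1.45
23,V,4p,-5.52,1.45
24,Cr,3d,-11.22,2.85
24,Cr,4s,-8.66,1.55
24,Cr,4p,-5.24,1.55
25,Mn,3d,-11.67,3.0
25,Mn,4s,-9.75,1.6
25,Mn,4p,-5.89,1.6
26,Fe,3d,-12.6,3.15
26,Fe,4s,-9.1,1.7
26,Fe,4p,-5.32,1.7
27,Co,3d,-13.18,3.3
27,Co,4s,-9.21,1.75
27,Co,4p,-5.29,1.75
28,Ni,3d,-13.49,3.45
28,Ni,4s,-9.17,1.8
28,Ni,4p,-5.15,1.8
29,Cu,3d,-14.0,3.6
29,Cu,4s,-11.4,1.85
29,Cu,4p,-6.06,1.85
30,Zn,3d,-15.0,3.75
30,Zn,4s,-12.41,1.9
30,Zn,4p,-6.53,1.9
31,Ga,4s,-15.023,1.4459
31,Ga,4p,-7.964,1.4459
32,Ge,4s,-16.683,1.6216
32,Ge,4p,-8.844,1.6216
33,As,4s,-18.094,1.7973
33,As,4p,-9.592,1.7973
34,Se,4s,-21.165,1.973
34,Se,4p,-11.22,1.973
35,Br,4s,-27.0,2.054
35,Br,4p,-13.1,2.054
36,Kr,4s,-24.9,2.3243
36,Kr,4p,-13.2,2.3243
37,Rb,5s,-6.806,0.55
37,Rb,5p,-3.608,0.55
38,Sr,5s,-7.885,0.7125
38,Sr,5p,-4.18,0.7125
39,Y,4d,-8.0,0.8108
39,Y,5s,-10.126,0.75
39,Y,5p,-5.5,0.75
40,Zr,4d,-8.55,0.9865
40,Zr,5s,-11.039,0.7875
40,Zr,5p,-5.5,0.7875
41,Nb,4d,-9.1,1.1622
41,Nb,5s,-13.28,0.825
41,Nb,5p,-5.5,0.825
42,Mo,4d,-9.65,1.3378
42,Mo,5s,-17.928,0.8625
42,Mo,5p,-5.5,0.8625
43,Tc,4d,-10.2,1.5135
43,Tc,5s,-15.77,0.9
43,Tc,5p,-5.5,0.9
44,Ru,4d,-10.75,1.6892
44,Ru,5s,-18.26,0.9375
44,Ru,5p,-5.5,0.9375
45,Rh,4d,-11.3,1.8649
45,Rh,5s,-18.924,0.975
45,Rh,5p,-5.5,0.975
46,Pd,4d,-11.85,2.0405
46,Pd,5s,-18.26,1.0125
46,Pd,5p,-5.5,1.0125
47,Ag,4d,-12.4,2.2162
47,Ag,5s,-16.019,1.05
47,Ag,5p,-5.5,1.05
48,Cd,4d,-12.95,2.3919
48,Cd,5s,-14.027,1.0875
48,Cd,5p,-5.5,1.0875
49,In,5s,-14.774,1.3375
49,In,5p,-7.832,1.3375
50,Sn,5s,-16.268,1.5
50,Sn,5p,-8.624,1.5
51,Sb,5s,-17.015,1.6625
51,Sb,5p,-9.02,1.6625
52,Te,5s,-17.43,1.825
52,Te,5p,-9.24,1.825
53,I,5s,-23.0,1.9
53,I,5p,-12.7,1.9
54,Xe,5s,-21.58,2.15
54,Xe,5p,-11.44,2.15
55,Cs,6s,-6.557,0.5238
55,Cs,6p,-3.476,0.5238
56,Ba,6s,-7.387,0.6786
56,Ba,6p,-3.916,0.6786
72,Hf,5d,-8.55,0.9125
72,Hf,6s,-10.79,0.75
72,Hf,6p,-5.5,0.75
73,Ta,5d,-9.1,1.075
73,Ta,6s,-12.45,0.7857
73,Ta,6p,-5.5,0.7857
74,W,5d,-9.65,1.2375
74,W,6s,-19.588,0.8214
74,W,6p,-5.5,0.8214
75,Re,5d,-10.2,1.4
75,Re,6s,-15.77,0.8571
75,Re,6p,-5.5,0.8571
76,Os,5d,-10.75,1.5625
76,Os,6s,-18.26,0.8929
76,Os,6p,-5.5,0.8929
77,Ir,5d,-11.3,1.725
77,Ir,6s,-18.26,0.9286
77,Ir,6p,-5.5,0.9286
78,Pt,5d,-11.85,1.8875
78,Pt,6s,-18.924,0.9643
78,Pt,6p,-5.5,0.9643
79,Au,5d,-12.4,2.05
79,Au,6s,-21.082,1.0
79,Au,6p,-5.5,1.0
80,Hg,5d,-12.95,2.2125
80,Hg,6s,-16.6,1.0357
80,Hg,6p,-5.5,1.0357
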