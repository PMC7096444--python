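# reaction: B11(p,aa)a  (proton-induced three-alpha breakup of boron-11)
# units: E_MeV	sigma_mb
# provenance: implementer-assembled working table.  The 0.6 MeV point is the
# Sikora & Weller (2016) anchor value of 1400 mb (exact); the remaining
# 0.6-4 MeV points are a smooth interpolation consistent with that
# evaluation's broad low-energy structure, and the 4-40 MeV points follow a
# TENDL-2017-style monotone decline.  Intended for desk-scale folding, not
# for evaluated-data work.
0.60	1400
0.65	1360
0.675	1340
0.70	1320
0.80	1260
0.90	1200
1.00	1150
1.20	1080
1.40	1030
1.60	1000
1.80	980
2.00	970
2.25	965
2.50	960
2.75	950
3.00	930
3.25	900
3.50	865
3.75	830
4.00	800
5.00	640
6.00	520
7.00	430
8.00	365
10.0	275
12.0	215
15.0	155
20.0	100
25.0	72
30.0	56
35.0	46
40.0	40
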