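# Synthetic annual mortality table (Gompertz-Makeham stand-in).
# qx(age) = 1 - exp(-(c + a*exp(b*age))) with a=3.7898e-5, b=0.090, c=0.0004.
# Calibrated so the base-case cohort's 30-year discounted life-years (4%)
# reproduce the modelled ~16.7; q(45) = 0.0026, close to the 2007 Norwegian
# population.  Not an official life table; supply an (age,qx) file to
# override.
age,qx
18,0.00059133
19,0.00060935
20,0.00062907
21,0.00065065
22,0.00067426
23,0.00070009
24,0.00072835
25,0.00075928
26,0.00079311
27,0.00083013
28,0.00087064
29,0.00091496
30,0.00096345
31,0.00101650
32,0.00107455
33,0.00113806
34,0.00120754
35,0.00128357
36,0.00136674
37,0.00145774
38,0.00155731
39,0.00166623
40,0.00178540
41,0.00191578
42,0.00205842
43,0.00221446
44,0.00238518
45,0.00257194
46,0.00277624
47,0.00299974
48,0.00324422
49,0.00351167
50,0.00380421
51,0.00412421
52,0.00447423
53,0.00485707
54,0.00527579
55,0.00573375
56,0.00623459
57,0.00678231
58,0.00738126
59,0.00803620
60,0.00875233
61,0.00953531
62,0.01039132
63,0.01132709
64,0.01234997
65,0.01346797
66,0.01468981
67,0.01602498
68,0.01748382
69,0.01907756
70,0.02081843
71,0.02271970
72,0.02479580
73,0.02706236
74,0.02953634
75,0.03223609
76,0.03518149
77,0.03839400
78,0.04189679
79,0.04571484
80,0.04987502
81,0.05440621
82,0.05933936
83,0.06470761
84,0.07054632
85,0.07689313
86,0.08378801
87,0.09127321
88,0.09939329
89,0.10819496
90,0.11772700
91,0.12804003
92,0.13918622
93,0.15121891
94,0.16419216
95,0.17816009
96,0.19317614
97,0.20929215
98,0.22655730
99,0.24501677
100,0.26471028
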