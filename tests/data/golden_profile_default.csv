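section_index,position_um,time_s,pO2_mmHg,pCO2_mmHg,saturation,o2_flux_ml_per_s
0,0,0,40,45,0.739519436875,1.8e-09
1,5,0.005,40.7810057241,44.7716584158,0.750482181128,1.77656982828e-09
2,10,0.01,41.589955585,44.5462890998,0.761296348239,1.75230133245e-09
3,15,0.015,42.4291273562,44.3239983985,0.771956425069,1.72712617931e-09
4,20,0.02,43.3009941815,44.1049013275,0.7824564476,1.70097017456e-09
5,25,0.025,44.2082428107,43.8891223141,0.792789962026,1.67375271568e-09
6,30,0.03,45.153792344,43.6767960104,0.802949982412,1.64538622968e-09
7,35,0.035,46.1408129013,43.468068178,0.812928944894,1.61577561296e-09
8,40,0.04,47.1727433093,43.263096643,0.822718658579,1.58481770072e-09
9,45,0.045,48.2533064242,43.0620523183,0.832310253548,1.55240080727e-09
10,50,0.05,49.386520062,42.8651202852,0.841694126707,1.51840439814e-09
11,55,0.055,50.5767005923,42.6725009154,0.850859886746,1.48269898223e-09
12,60,0.06,51.8284550131,42.4844110074,0.859796300207,1.44514634961e-09
13,65,0.065,53.1466556548,42.3010848925,0.868491241713,1.40560033036e-09
14,70,0.07,54.5363894504,42.1227754446,0.876931652765,1.36390831649e-09
15,75,0.075,56.0028709134,41.9497548971,0.885103515536,1.3199138726e-09
16,80,0.08,57.5513045164,41.7823153278,0.892991850518,1.27346086451e-09
17,85,0.085,59.1866782618,41.6207686216,0.90058075022,1.22439965214e-09
18,90,0.09,60.9134663085,41.465445646,0.90785346502,1.17259601074e-09
19,95,0.095,62.7352156197,41.3166942956,0.914792561825,1.11794353141e-09
20,100,0.1,64.6539916719,41.1748759639,0.921380180839,1.06038024984e-09
21,105,0.105,66.6696645649,41.040359905,0.92759841932,9.99910063052e-10
22,110,0.11,68.779034161,40.9135148785,0.93342987204,9.36628975169e-10
23,115,0.115,70.9748269617,40.7946974651,0.938858353132,8.70755191149e-10
24,120,0.12,73.2446532208,40.6842365653,0.943869809359,8.02660403376e-10
25,125,0.125,75.5700898205,40.5824139275,0.948453406642,7.32897305384e-10
26,130,0.13,77.9261397858,40.4894411876,0.952602727894,6.62215806425e-10
27,135,0.135,80.2813804238,40.4054348508,0.956316964501,5.91558587287e-10
28,140,0.14,82.5990970706,40.3303918369,0.959601928423,5.22027087881e-10
29,145,0.145,84.8395555222,40.2641693413,0.962470679252,4.54813334335e-10
30,150,0.15,86.963280298,40.2064733428,0.964943576376,3.9110159106e-10
31,155,0.155,88.9348476916,40.156859589,0.967047646194,3.31954569253e-10
32,160,0.16,90.7264262144,40.1147490155,0.968815287631,2.78207213567e-10
33,165,0.165,92.3202669189,40.07945664,0.970282485623,2.30391992434e-10
34,170,0.17,93.7096194724,40.0502299331,0.971486807391,1.88711415827e-10
35,175,0.175,94.8980153525,40.0262906755,0.972465481322,1.53059539425e-10
36,180,0.18,95.8973005125,40.0068740879,0.973253801139,1.23080984625e-10
37,185,0.185,96.7250363409,39.9912604729,0.973883990893,9.82489097717e-11
38,190,0.19,97.4018753059,39.9787969664,0.974384553965,7.79437408225e-11
39,195,0.195,97.9493361272,39.9689093012,0.97478004521,6.15199161834e-11
40,200,0.2,98.3881745098,39.9611051039,0.975091162226,4.83547647045e-11
41,205,0.205,98.7373596038,39.9549709908,0.975335044156,3.78792118848e-11
42,210,0.21,99.0135577004,39.950165769,0.975525681329,2.95932689891e-11
43,215,0.215,99.2309855035,39.9464116724,0.975674363274,2.30704348936e-11
44,220,0.22,99.4015009759,39.9434850393,0.975790117199,1.79549707239e-11
45,225,0.225,99.5348261535,39.9412073357,0.975880109328,1.39552153938e-11
46,230,0.23,99.6388272306,39.9394370268,0.975949996257,1.08351830814e-11
47,235,0.235,99.7198043023,39.9380625141,0.976004223077,8.40587093172e-12
48,240,0.24,99.7827636263,39.9369961753,0.976046270672,6.51709121152e-12
49,245,0.245,99.8316592278,39.9361694403,0.976078857454,5.05022316735e-12
50,250,0.25,99.8695994197,39.935528787,0.976104101884,3.91201740833e-12
51,255,0.255,99.8990188257,39.9350325224,0.976123652153,3.02943522906e-12
52,260,0.26,99.9218190413,39.9346482191,0.976138788941,2.34542876009e-12
53,265,0.265,99.9394821079,39.9343506863,0.97615050637,1.81553676277e-12
54,270,0.27,99.9531611388,39.9341203738,0.976159575532,1.40516583586e-12
55,275,0.275,99.963752156,39.9339421195,0.976166594164,1.08743531931e-12
56,280,0.28,99.9719507094,39.9338041713,0.976172025411,8.41478719283e-13
57,285,0.285,99.978296309,39.9336974243,0.976176228,6.51110730922e-13
58,290,0.29,99.9832071793,39.9336148267,0.976179479707,5.03784620139e-13
59,295,0.295,99.9870073741,39.9335509184,0.976181995577,3.89778778293e-13
60,300,0.3,99.9899478897,39.9335014725,0.976183942062,3.01563308698e-13
61,305,0.305,99.9922230821,39.9334632172,0.976185447987,2.33307536869e-13
62,310,0.31,99.9939834156,39.9334336207,0.976186613045,1.80497532224e-13
63,315,0.315,99.9953453557,39.9334107234,0.976187514378,1.3963933031e-13
64,320,0.32,99.9963990396,39.9333930092,0.976188211675,1.08028810779e-13
65,325,0.325,99.9972142215,39.9333793051,0.97618875112,8.3573354603e-14
66,330,0.33,99.9978448771,39.9333687033,0.976189168443,6.46536861668e-14
67,335,0.335,99.9983327707,39.9333605015,0.97618949129,5.00168795103e-14
68,340,0.34,99.998710216,39.9333541566,0.976189741048,3.86935190562e-14
69,345,0.345,99.9990022142,39.933349248,0.976189934262,2.99335741807e-14
70,350,0.35,99.9992281078,39.9333454508,0.976190083734,2.31567670035e-14
71,355,0.355,99.9994028613,39.9333425132,0.976190199366,1.79141623102e-14
72,360,0.36,99.9995380519,39.9333402407,0.976190288819,1.3858444472e-14
73,365,0.365,99.999642636,39.9333384826,0.97619035802,1.07209187952e-14
74,370,0.37,99.9997235428,39.9333371226,0.976190411554,8.29371617939e-15
75,375,0.375,99.9997861325,39.9333360705,0.976190452968,6.41602510476e-15
76,380,0.38,99.999834552,39.9333352566,0.976190485006,4.96343944567e-15
77,385,0.385,99.9998720094,39.9333346269,0.97619050979,3.83971715623e-15
78,390,0.39,99.9999009865,39.9333341399,0.976190528964,2.97040463915e-15
79,395,0.395,99.9999234032,39.933333763,0.976190543796,2.29790408079e-15
80,400,0.4,99.9999407447,39.9333334715,0.976190555271,1.77765753651e-15
81,405,0.405,99.9999541602,39.933333246,0.976190564147,1.37519488486e-15
82,410,0.41,99.9999645383,39.9333330716,0.976190571014,1.06384986753e-15
83,415,0.415,99.9999725669,39.9333329366,0.976190576326,8.22993508676e-16
84,420,0.42,99.9999787778,39.9333328322,0.976190580436,6.3666715211e-16
85,425,0.425,99.9999835825,39.9333327515,0.976190583615,4.92525208617e-16
86,430,0.43,99.9999872994,39.933332689,0.976190586074,3.81017081885e-16
87,435,0.435,99.9999901749,39.9333326406,0.976190587977,2.94754494368e-16
88,440,0.44,99.9999923993,39.9333326032,0.976190589449,2.28021826976e-16
89,445,0.445,99.9999941201,39.9333325743,0.976190590587,1.76397492391e-16
90,450,0.45,99.9999954513,39.9333325519,0.976190591468,1.36460932776e-16
91,455,0.455,99.9999964811,39.9333325346,0.97619059215,1.05566067221e-16
92,460,0.46,99.9999972778,39.9333325212,0.976190592677,8.16658043412e-17
93,465,0.465,99.9999978941,39.9333325109,0.976190593085,6.31765861847e-17
94,470,0.47,99.9999983709,39.9333325029,0.9761905934,4.88733649107e-17
95,475,0.475,99.9999987397,39.9333324967,0.976190593644,3.78083739871e-17
96,480,0.48,99.999999025,39.9333324919,0.976190593833,2.92485358155e-17
97,485,0.485,99.9999992458,39.9333324882,0.976190593979,2.26266392289e-17
98,490,0.49,99.9999994165,39.9333324853,0.976190594092,1.75039545081e-17
99,495,0.495,99.9999995486,39.9333324831,0.976190594179,1.35410340718e-17
100,500,0.5,99.9999996508,39.9333324814,0.976190594247,0
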