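time_cycles,survival
0.0,0.98
0.7061768819568488,0.9676323661341832
1.4123537639136976,0.9454001117634716
2.118530645870546,0.9112242734611583
2.824707527827395,0.8602895135397142
3.5308844097842442,0.8285272023043729
4.237061291741092,0.7763210326126038
4.943238173697941,0.740815511599265
5.64941505565479,0.7210052495745897
6.355591937611639,0.7020882031785798
7.0617688195684885,0.6344920269351001
7.767945701525337,0.6344920269351001
8.474122583482185,0.6030556262827371
9.180299465439035,0.589256548424788
9.886476347395883,0.5554704169519543
10.592653229352733,0.508935205788444
11.29883011130958,0.49634645923789816
12.005006993266429,0.46180781990943304
12.711183875223279,0.44308269658132227
13.417360757180127,0.4049160682897997
14.123537639136977,0.3642613318314558
14.829714521093825,0.3642613318314558
15.535891403050673,0.33454940503036645
16.242068285007523,0.3165584947698072
16.94824516696437,0.30995477468809834
17.65442204892122,0.30338157322355663
18.36059893087807,0.28026316356734177
19.06677581283492,0.27874441079693535
19.772952694791766,0.24835466626985794
20.479129576748615,0.21116850279014374
21.185306458705465,0.21116850279014374
21.89148334066231,0.20661842317887888
22.59766022261916,0.19376497651503
23.30383710457601,0.18719423849604322
24.010013986532858,0.181926568099009
24.716190868489708,0.18085469958573047
25.422367750446558,0.17400122011317276
26.128544632403404,0.1720642447519861
26.834721514360254,0.12672227244473544
27.540898396317104,0.12672227244473544
28.247075278273954,0.10793619242606238
28.9532521602308,0.1038984983845064
29.65942904218765,0.1038984983845064
30.3656059241445,0.07307059511704914
31.071782806101346,0.07004012663233027
31.777959688058196,0.07004012663233027
32.484136570015046,0.07004012663233027
33.190313451971896,0.06777345638604054
33.89649033392874,0.06777345638604054
34.60266721588559,0.03659112458310696
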