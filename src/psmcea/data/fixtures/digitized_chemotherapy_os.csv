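time_cycles,survival
0.0,1.0
0.6169920779609805,0.9995406469666166
1.233984155921961,0.9995406469666166
1.8509762338829416,0.9796060765554782
2.467968311843922,0.9550613791295671
3.0849603898049027,0.9409547577753674
3.7019524677658833,0.9219652842392623
4.318944545726864,0.8639762077141679
4.935936623687844,0.8479245283018871
5.552928701648825,0.8072329110744516
6.1699207796098055,0.8061635220125789
6.786912857570786,0.7562126162720632
7.4039049355317665,0.7455824024475244
8.020897013492746,0.6969811320754719
8.637889091453728,0.6964281571423045
9.254881169414709,0.683079488241204
9.871873247375689,0.6677987421383649
10.488865325336668,0.638494475295415
11.10585740329765,0.638494475295415
11.722849481258631,0.6368609606952138
12.339841559219611,0.6279518613601927
12.95683363718059,0.5962294058374639
13.573825715141572,0.594351214060174
14.190817793102553,0.5814305280794815
14.807809871063533,0.5451466146979803
15.424801949024513,0.5451466146979803
16.041794026985492,0.5208348200671785
16.658786104946476,0.5208348200671785
17.275778182907455,0.48874153013232197
17.892770260868435,0.4801230946044454
18.509762338829418,0.47816472930967
19.126754416790398,0.4445181084350201
19.743746494751377,0.43179775304835966
20.360738572712357,0.4102440791077109
20.977730650673337,0.4102440791077109
21.59472272863432,0.38834693725223624
22.2117148065953,0.37813011971285493
22.82870688455628,0.3628496361877973
23.445698962517262,0.3449414826221485
24.062691040478242,0.30641033684934726
24.679683118439222,0.28799168244191586
25.2966751964002,0.28107865016253036
25.91366727436118,0.27794061072379145
26.530659352322164,0.25887251411972856
27.147651430283144,0.2553901971350278
27.764643508244124,0.22573995057079704
28.381635586205107,0.19371677982502075
28.998627664166087,0.19371677982502075
29.615619742127066,0.17602656282266912
30.232611820088046,0.15573712742698542
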