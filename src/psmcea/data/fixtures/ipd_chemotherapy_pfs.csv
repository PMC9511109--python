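time_cycles,event
4.148003629184451,1
6.555342411140376,1
0.5437068195757323,1
8.74376126257586,1
6.02267920905197,1
5.975445041127546,1
13.376787142276102,1
1.5897803910379478,1
4.350664972514642,1
7.595376283641125,1
9.142840633935457,1
10.084385981859052,1
17.55077425405123,1
2.7159000030673197,1
8.102252958712842,1
8.716795023209544,1
10.789688908539345,1
2.0036767862945655,1
19.05193037432468,1
3.780682408067361,1
7.642334133400523,1
12.762334314633495,1
7.682502908507887,1
8.730196024269748,1
13.716711297926702,1
3.3902510224233753,1
0.5836961670024154,1
4.9027965737373345,1
2.182181351671676,1
2.077788631914938,1
16.009140010966263,0
0.6570793939214086,1
21.80299762279688,1
0.3448415415930928,1
4.538809225782292,1
16.994216021906485,0
8.100839269245427,1
16.245519779137922,1
12.873298182593597,1
25.266993725997413,1
12.553853525783026,1
4.608080919682901,1
2.572939549672431,1
0.2762101985781546,1
6.537686356373738,1
17.920228170266764,1
6.666652965307612,1
15.569267608413941,1
3.4619117773037535,1
5.445182125918869,1
7.44866156764337,1
5.064973890534622,1
8.352505975849596,1
8.73628481307785,1
11.20974203430252,1
7.08053609670904,1
1.9811622710816743,1
14.342158751632596,1
3.916751246629582,1
16.29549550407946,1
13.986932401158919,1
13.690568099732209,1
6.195121118395985,1
0.5759399517185217,1
4.314289456037547,1
1.908369447585476,1
3.098689315016976,1
12.091768007937757,1
6.308150075828343,1
1.3585482633378658,1
3.9999929885422603,1
13.031003529687036,1
8.11320967929704,1
2.9385959753532602,1
6.620525902097281,1
1.517098088687608,1
9.087466418632143,1
2.223495911427151,1
2.459919641653523,1
9.991205217865842,1
7.435831910592118,1
2.053295321224887,1
9.931618983374761,1
14.152992128122255,1
12.818731015594345,1
12.241940414787058,1
0.8543111206178844,1
9.241276900636125,1
3.3304840419129675,1
13.301129501925141,1
0.3489022639755932,1
16.267741311148853,1
4.822658630392459,1
17.979602337387696,0
3.116140211038454,1
9.886150302003212,1
17.406993796982096,1
5.1794169855968555,1
4.917403831305484,1
11.123389543923023,1
6.477280032572975,1
12.585745159904906,1
2.6226400895028386,1
4.448445893719794,1
4.78766990881861,1
10.980168219504911,1
0.9306478718178622,1
11.629106867684389,1
4.920297969658479,1
8.89907275536435,1
17.516278942079303,1
15.005763346890781,1
5.201372651102111,1
8.426975285614459,1
3.2162127567880567,1
3.4831247976737068,1
7.839488445254916,1
6.453531777567739,1
7.6503496899099,1
5.70288971685781,1
14.57962768948107,1
16.515244542306245,1
17.55916618641728,1
7.721912181446605,1
3.8040212188777023,1
0.9710806694201575,1
17.81250921505367,0
6.942526069365252,1
5.112090204095898,1
13.407185919954793,1
4.225525600598332,1
2.6440140676332424,1
18.56740864361339,1
10.032180617878554,1
0.9076514097499496,1
23.284403537157903,1
2.531504545362289,1
7.882531039856058,1
7.2190822820605804,1
13.383790953331621,1
4.482913709380632,1
1.0417192391813843,1
7.368888271920494,1
14.206144727008306,1
3.1478801782977888,1
5.499188000783934,1
3.615746743185613,1
4.993841594308874,1
15.372531945036862,1
1.3608689761800916,1
4.331771408867143,1
15.057384653226212,0
20.191913977939638,1
2.1171698656201414,1
9.224725834272222,1
1.5221953047997936,1
3.0157460158214255,1
9.625420432209673,1
3.8465663840518074,1
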