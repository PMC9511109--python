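time_cycles,event
19.151294005647514,1
18.755211650895987,0
17.339682783213085,1
23.425938108754167,1
28.27200870815208,1
4.021226732603801,1
3.6670348427147523,1
8.561091484672824,1
34.85872242163965,0
3.2935997249974447,1
25.845488083700424,1
24.92862860924383,1
24.16841939954505,0
29.880246137703125,0
7.434701417061886,1
20.347751144145068,0
0.349012891543811,1
19.829780143208247,0
14.711967907941762,0
27.166659445251113,0
15.530831244302814,1
28.233915812277104,0
5.018256161863128,1
14.656402853977035,1
23.014997083489355,0
21.90490635577926,1
13.446544216793935,1
8.107107838566387,1
5.380940577929399,1
21.16568318306925,1
10.847238552379938,1
8.38981466642527,1
30.08676254637092,0
13.95222739204431,1
9.562044176709986,1
19.06004029885394,1
15.938812130334394,0
17.663991104381992,0
8.022186745648415,1
5.54587335504374,1
6.319215440618039,1
1.3276064372198182,1
15.79939392541076,1
35.40832576409745,0
3.344668980441754,1
19.05992054108679,1
15.003660405056493,0
17.768554008748712,0
5.842969767325972,1
9.744895077154311,1
6.159379243013211,1
20.25625547446161,0
7.120480995604313,1
35.251709155277595,0
27.529125835156123,1
8.505518817959574,1
24.333190144587505,1
7.816410537594902,1
27.469005117656152,1
21.03071899181984,1
17.44982358893129,0
3.4262544027290542,1
6.514624870873347,1
18.15404711406404,0
6.587540587936074,1
9.389093636104366,1
18.986221720317776,1
3.856637100255448,1
30.232611820088046,1
23.732908577909534,1
1.8848572442817046,1
21.86533841569229,1
14.122057349183912,1
3.307133335274553,1
20.169276821301725,1
22.043554560480644,0
23.960801913962456,1
27.708841169330405,1
33.7661178401143,0
35.3416258977776,0
8.735624341865384,1
14.015363771897562,1
12.631731524983348,1
4.456994274238847,1
5.450469954277606,1
5.077556785384982,1
24.410714480194592,0
12.443995311047681,1
6.621751572933541,1
5.809878080081589,1
11.011243074214416,1
17.266860225323654,1
15.945580360704785,0
29.79163323500239,0
14.371569926720086,1
5.119991166608684,1
4.983019993702608,1
1.1844766242022005,1
3.933318538310087,1
37.951340293738525,0
5.128729182771011,1
3.080781572953073,1
22.20044123295503,0
2.341689648105143,1
22.53293811755198,1
21.673028259450966,1
25.249461603893515,1
7.713110142661835,1
22.849157757433957,1
3.853576498297277,1
32.14701961530367,0
2.9258506807809974,1
27.898954034625454,1
14.546213143632144,1
15.022492957425367,0
14.072564571301355,1
15.732232642841609,1
12.68944009573282,1
17.860017685927808,1
10.209440820511198,1
4.2421745178831705,1
7.990452202331512,1
37.581142320393425,0
18.635842568197198,1
1.744377719367626,1
29.24578618829541,1
27.42144261353298,0
34.90532402318431,0
26.381596390706505,1
38.8114988405198,0
7.298037013475513,1
12.67119454352378,1
28.62165376521459,0
19.604811300980117,1
5.008417290654249,1
24.97250694492002,1
20.141936066756248,1
24.388160644769517,1
15.704811139530609,0
37.594679756624025,0
26.20939550043437,0
28.683162322591787,1
5.687741871702865,1
24.683512734293515,0
4.564373817909479,1
14.784245812960311,1
9.01122880078122,1
18.420779780792007,1
16.77680969171986,1
11.734434696333626,1
3.054179879895154,1
9.272350681999901,1
18.452403213043482,1
23.143945697961676,0
6.88031456526333,1
20.914589075926887,1
22.021651320181324,1
30.366975764635352,0
23.330033122244497,1
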