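time_cycles,survival
0.0,1.0
0.5156529331836207,0.9848214049392459
1.0313058663672414,0.9450774990568804
1.546958799550862,0.9041343784422702
2.062611732734483,0.8607217564880583
2.5782646659181037,0.8214579024294554
3.093917599101724,0.8024684288933505
3.609570532285345,0.7256114278399548
4.125223465468966,0.6844025157232702
4.640876398652586,0.6437108984958355
5.156529331836207,0.6174842767295597
5.672182265019828,0.567533370989044
6.187835198203448,0.5569031571645054
6.703488131387069,0.48915747479756744
7.21914106457069,0.48915747479756744
7.734793997754311,0.44408577754938056
8.250446930937931,0.4225157232704401
8.766099864121552,0.35233095328283637
9.281752797305172,0.35233095328283637
9.797405730488794,0.3349741682423834
10.313058663672415,0.30090783620296
10.828711596856035,0.28805330520853306
11.344364530039655,0.2765701163528467
11.860017463223276,0.2765701163528467
12.375670396406896,0.25098473313817904
12.891323329590518,0.22939186615685947
13.406976262774139,0.19176391787584318
13.922629195957759,0.17877643563874396
14.43828212914138,0.1321207369059579
14.953935062325,0.13103398991008408
15.469587995508622,0.1305089142887292
15.985240928692242,0.11922655115993021
16.500893861875863,0.10017323770271434
17.016546795059483,0.08278157079121198
17.532199728243103,0.08278157079121198
18.047852661426724,0.05933977178542464
18.563505594610344,0.05933977178542464
19.079158527793965,0.0460081548348376
19.59481146097759,0.0460081548348376
20.11046439416121,0.031056694375517772
20.62611732734483,0.031056694375517772
21.14177026052845,0.031056694375517772
21.65742319371207,0.031056694375517772
22.17307612689569,0.02354486879171416
22.68872906007931,0.020536735688378216
23.20438199326293,0.020536735688378216
23.72003492644655,0.005718642284458449
24.235687859630172,0.005718642284458449
24.751340792813792,0.0049851573882974485
25.266993725997413,0.0
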