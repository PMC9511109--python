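time_cycles,survival
0.0,0.9800661830670913
0.7291008005829757,0.9800661830670913
1.4582016011659513,0.9766501117634716
2.187302401748927,0.9674742734611583
2.9164032023319026,0.9446645135397137
3.6455040029148784,0.9316522023043735
4.374604803497854,0.8950710326126042
5.1037056040808295,0.8720655115992649
5.832806404663805,0.8647552495745896
6.561907205246781,0.8645882031785801
7.291008005829757,0.8094920269351003
8.020108806412733,0.8094920269351003
8.749209606995707,0.7749306262827373
9.478310407578684,0.7520509826883714
10.207411208161659,0.7520509826883714
10.936512008744636,0.7151852057884444
11.66561280932761,0.6994714592378986
12.394713609910585,0.6993078199094331
13.123814410493562,0.6805826965813222
13.852915211076537,0.6580410682897999
14.582016011659514,0.6234694074705329
15.311116812242489,0.6234694074705329
16.040217612825465,0.6054224593392598
16.769318413408442,0.5688788579444797
17.498419213991415,0.5402664287298063
18.22752001457439,0.522115709211393
18.95662081515737,0.5027118465108005
19.68572161574034,0.5027118465108005
20.414822416323318,0.4816082997194333
21.143923216906295,0.4507188501844283
21.87302401748927,0.4507188501844283
22.602124818072244,0.4493331226424817
23.33122561865522,0.40632994841159975
24.060326419238198,0.4043000042916338
24.78942721982117,0.39981077308108964
25.518528020404148,0.39981077308108964
26.247628820987124,0.39981077308108964
26.9767296215701,0.3946225866439753
27.705830422153074,0.36432779414806205
28.43493122273605,0.36432779414806205
29.164032023319027,0.34314445523503506
29.893132823902,0.34314445523503506
30.622233624484977,0.34314445523503506
31.351334425067954,0.32878615824458685
32.08043522565093,0.31071258322270107
32.80953602623391,0.309999505769523
33.538636826816884,0.309999505769523
34.26773762739985,0.30482609594978227
34.99683842798283,0.30482609594978227
35.72593922856581,0.28523488293852245
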