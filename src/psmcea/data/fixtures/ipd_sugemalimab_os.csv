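time_cycles,event
18.614998223908863,1
15.380923965414919,0
12.78436517159539,1
12.721032799926624,1
14.26499563772909,1
29.860856099551583,0
18.639969208709292,0
21.241118186170837,1
18.531562494871842,0
19.12852523027787,0
11.243536881489446,1
2.5584888330053603,1
11.044277623746222,1
3.688943763290662,1
35.957242339273826,0
0.322993479143689,1
27.090952872724074,0
15.871359622547606,1
37.982317070499015,0
12.255543161292847,1
4.853292159637962,1
35.47368360600731,0
19.605169851316774,0
25.24962499961633,0
23.045092002872984,1
13.654754658836847,1
15.944915563102239,0
19.208800594373212,1
3.9430015589581195,1
1.8651345053716852,1
16.267919659437187,1
36.92700896906494,0
8.09466809550079,1
16.70876099852811,0
21.138425950071948,1
3.1155541046919613,1
14.974182097739764,0
34.72905050577868,0
12.802484967193735,1
17.765177312272034,1
10.589444109781542,1
17.23386972656127,1
21.434699035579296,0
20.888989291606723,0
5.0846421046367105,1
5.439517637870808,1
8.66162024426587,1
15.280846045421171,1
0.1723473834657339,1
1.4468462810102274,1
6.967099140741073,1
4.005322852763101,1
7.277116527031511,1
7.403486880867915,1
12.486938576234436,1
38.38305292668345,0
32.96802391951849,0
22.104839622248658,0
17.582841485341806,1
28.497966310420132,0
14.29748223745417,1
8.452347614349934,1
18.00888371704382,1
4.926529538114451,1
1.0843201903138349,1
20.474975759865057,0
6.906173465832275,1
17.756691585229625,0
17.39792017930808,1
9.399585696681624,1
20.484893422888355,0
5.519567212052152,1
32.18588517626553,0
6.37749187069442,1
17.08498185908263,0
33.377223351410834,0
37.858112559896945,0
3.54633284745383,1
14.919758433115213,1
30.491941185459687,0
6.396500621067385,1
8.159453032533268,1
36.835050594883604,0
5.154219319786579,1
36.861307240791845,0
18.21544957755547,1
8.712562652679253,1
21.145107252925204,1
8.99702356453,1
35.72593922856581,1
18.221881988229192,1
20.200007742050705,1
14.482051136690554,0
39.02980192528259,0
6.383385598309625,1
8.524972594818644,1
8.186007609571739,1
9.402710072633395,1
21.285495676911232,0
22.26340866582034,0
33.190229943893044,0
28.53792089123816,0
16.06124132347129,0
7.414331133460342,1
13.524761660232071,1
28.282107578092848,0
15.91785489238712,1
31.00629666799327,0
35.07128438257766,0
1.9436054479917737,1
17.027930325592276,1
16.872947322794765,0
14.761076275716487,0
20.75282070406404,1
26.30510742080771,0
12.821535443304787,1
25.743729810109837,0
11.40997838246943,1
6.754117071171594,1
16.294176790575747,0
18.526266331336036,0
1.6288488842717517,1
19.85388229285402,1
6.8375140017158325,1
24.320686264618175,0
26.352132039024728,1
3.915784547664812,1
20.230387663353955,0
1.1975134114418955,1
1.5435199382495037,1
19.702365405220846,0
8.211643042864724,1
13.175387111993132,1
19.32496148806351,0
0.954567019787719,1
16.64249278360481,1
19.882775278929774,0
35.853871291278836,0
14.839167753260536,1
23.259467405039363,1
27.255688947329336,0
2.454097553086695,1
22.22484350547628,0
7.004018597406963,1
32.777295314148226,1
30.63904176014632,0
13.872321284869171,1
19.3375295445759,0
3.5299867789381825,1
24.945954034610512,0
2.6675617903726603,1
37.25437372049899,0
22.18182208397302,1
20.803076519354583,0
19.102672758024678,1
20.316395652510067,0
31.900063457364976,0
7.329108202155568,1
5.307146942712271,1
8.898361277397875,1
23.304947160410343,1
17.36556643880916,0
16.29371041968245,1
17.997979245424414,1
21.24114656187196,1
8.763984064117356,1
3.191542854075559,1
38.075205982376254,0
14.045695140787661,1
7.998987374069921,1
33.05376981374696,0
19.45354105919518,0
24.661040440698052,0
39.13028798572426,0
35.94518284227547,0
23.224281628513065,1
10.778813479338941,1
20.519179802272426,1
12.69201689614432,1
16.58890015914787,1
5.586753003845645,1
20.010518997011197,1
13.688309139021962,1
16.706639886979882,1
16.868238471341463,1
12.149044141439092,1
27.894876875442925,0
20.382182226313965,0
19.119855517923877,1
6.967195810835666,1
6.395504433938874,1
20.807989258957846,0
34.79242679290667,0
14.597875392283989,0
22.197926197216002,1
10.84511234968414,1
8.135046576856608,1
7.662780521570781,1
2.999173227239472,1
15.39736396831329,0
23.26146189054511,1
14.253961798945975,1
17.171293275794447,1
15.507898614791443,1
6.783119707521531,1
38.63680662716351,0
11.610175025179338,1
16.301681647718773,1
6.725769452223157,1
0.6880360697492146,1
26.996566712933866,0
24.52223542563435,1
20.824443715657463,0
7.559207749078652,1
26.940742808775234,0
21.78072538305766,0
26.50654153017389,0
25.87060215622851,0
12.281912148086603,1
24.432450263654136,1
0.31846995818036467,1
13.968693205153272,1
22.380726339345248,0
24.57321584852034,0
25.57229255505531,1
34.771899993678375,0
4.188248595535509,1
19.32212838528226,0
15.530627815271721,0
31.006974343140616,0
9.106677555937559,1
32.63864036643287,1
16.174731201847766,1
14.397661653576113,1
27.45355166930956,1
32.06370224304575,1
14.822571916611167,0
36.50582367434369,0
21.334123699162916,0
18.216527748272938,1
17.096702977583544,1
37.578550448388526,0
16.386529428276685,0
0.01733714668817315,1
9.169725981157752,1
20.40724154704718,0
14.092366642365604,1
34.17042717148807,0
14.83777949448187,1
17.20788380510625,1
11.455624134163923,1
15.011542603290415,0
29.866665279182527,1
12.975565017099928,1
34.97176067684447,0
38.570111070167115,0
24.79376153046706,0
0.6687135987493655,1
5.644699919952848,1
30.173486080804636,0
24.882422062542357,1
15.245435303216247,0
22.802561364066353,1
23.72442152296453,0
16.78920793592843,0
4.4618992521671865,1
20.855050229005844,0
29.60057992843541,0
18.360672693941773,0
16.58511188574034,1
0.3034594654422882,1
28.13821203664937,0
10.879269851262217,1
9.441648438001357,1
26.77255766087014,1
27.977798735248616,1
2.3872213847656742,1
24.886690565397664,0
12.619423400600825,1
28.178542660124947,1
23.62305732391893,0
19.333869938221003,0
16.61369738975389,0
26.58904154600112,0
31.368314124795948,0
7.767397287178102,1
22.984634869565554,1
30.878339206209343,1
9.69575754910321,1
3.7171113085230005,1
36.36650923046379,0
16.530878216722517,1
17.126982682642062,1
12.805056188130344,1
21.077849703130244,0
4.209725066394116,1
15.790620694743081,1
18.98393627236555,0
20.027818451827347,1
20.541485532646476,0
14.851820353704476,0
31.353347452549222,0
28.53594504003058,1
23.440899181482248,0
11.54530589048057,1
15.697487913956063,0
16.31475604098064,1
15.315990598574825,0
7.795073221959225,1
18.405168988249784,1
15.333300018497347,0
28.956353291743042,0
11.385340952512736,1
38.663371141038404,0
16.24728388134995,1
16.96146013881618,1
10.20916631564923,1
3.6011853186056677,1
15.36816937955497,0
33.57960648448866,0
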