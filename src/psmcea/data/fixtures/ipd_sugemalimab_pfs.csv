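time_cycles,event
10.287977684444655,1
3.05072809583746,1
15.986722199715489,1
6.393980637540635,1
20.65923110174545,0
20.34028097047231,1
5.897485379366563,1
14.747911082699595,1
9.526206347720729,1
10.014009708747905,1
8.450465147129725,1
6.451553742851339,1
1.5410551732312845,1
13.391454337594709,1
0.7845644970072575,1
7.764648739763764,1
11.465317646969607,1
11.32212699320016,1
13.469373067672032,1
19.152084588487565,0
22.124852975699653,1
18.44836025190454,1
6.10567290808705,1
16.21955154896261,0
1.578588157776307,1
5.05957994367585,1
9.245473029936392,1
1.2592282454016135,1
1.3454150310172062,1
25.224538111437955,1
34.60266721588559,1
26.811375257651484,0
2.654931715823271,1
3.5034945160887205,1
11.814817273012094,1
13.176978107941588,1
11.202470418105548,1
3.6152744963989862,1
22.337342942895287,0
7.622448690896035,1
14.310365129459013,1
11.382716194606905,1
18.670610633229316,1
0.9040086255986801,1
36.567093443983566,0
3.598779320670109,1
5.651844368846634,1
22.311917581022335,0
1.583259735474676,1
0.608264181827199,1
13.691776270572646,1
5.548189188543279,1
4.030572162668736,1
28.86582418098152,1
5.4978400062718435,1
18.410086190658618,1
6.6342542180041395,1
6.561252318933123,1
0.34260432840130245,1
15.64138169420583,1
23.27864207971605,0
14.974187596704496,0
19.247415274912644,1
11.088572689446442,1
9.640088171994694,1
8.516935558941382,1
24.13175624165169,0
0.5367439859944585,1
2.7515251720583724,1
11.310445086980552,1
2.6977285853480213,1
0.4889862579187913,1
8.113106943939652,1
6.839603389005482,1
2.0041154569171105,1
11.4794785313236,1
16.628544445291116,1
6.755916617767687,1
20.548534641952834,0
9.8230201286693,1
4.3938367119979045,1
28.53501657073609,0
3.154854534567037,1
14.149213106589661,1
6.639327215751221,1
4.254668168591674,1
8.65913627093881,1
4.823087215178773,1
29.88869581748882,1
5.911053696022098,1
8.054236226725997,1
15.99395282027471,0
1.0981894098208327,1
3.420003816873728,1
23.180349666598282,0
13.635427758708822,1
17.616529220552,1
25.58086621850226,0
15.280376833845601,1
11.898260208776554,1
2.318194509829318,1
2.5864504392082757,1
8.33742389118676,1
22.880860308554876,0
8.327370330142084,1
2.8809010741375767,1
18.025682234934933,0
1.2573427877666565,1
11.802247567000428,1
7.704830915814757,1
10.112858936331829,1
24.8757217899503,1
17.684011822830414,1
12.436469829181016,1
2.3357673512578776,1
3.687440396883417,1
19.569152280195812,0
10.631809762479813,1
20.791859313537692,1
24.210189674635956,0
14.013385694054163,1
11.284008209827375,1
4.425328576772137,1
18.492245248473534,1
15.25605336178824,1
14.217572078800426,1
19.116280465929613,1
37.07634559914423,0
25.586921429905864,1
9.762341944205565,1
22.68763428699751,1
20.17332535981835,1
9.802232124294843,1
13.207631358244065,1
14.296515511749433,1
1.987614216405287,1
12.799165628247536,1
25.0561895345978,0
2.2350164878445855,1
4.970970734793278,1
13.830201537477024,1
13.831334765592416,1
1.3303006298430602,1
2.0040998700915766,1
7.018571970400124,1
11.463511813274241,1
13.23815891445193,1
6.80738040071598,1
3.2364851889796795,1
5.787904814887611,1
16.15776325711593,1
16.104955913152615,1
5.898187793170884,1
1.9029668428253248,1
27.299703500768317,1
9.379742824581719,1
29.253328472313235,1
12.232767396328237,1
10.497464051273004,1
7.654848886681567,1
4.618940752635842,1
20.460725733242242,0
9.347035945672793,1
15.645425587282588,1
23.017318568520952,0
11.344896660593342,1
9.235302242426272,1
17.14722564059803,0
0.6240237628536845,1
34.57923613763568,1
27.72921734339454,0
13.453852922950261,1
11.630093115367398,1
2.6030879796339867,1
17.61978336916665,1
18.785493337653083,1
3.132062073277405,1
7.504607849798555,1
32.43321130327263,0
6.729284968290741,1
18.661417239202514,1
30.033777475989698,1
26.77272436417134,1
12.278324123982632,1
6.185691908099556,1
3.994486471354885,1
8.598182212872938,1
15.28290046262969,1
1.4206724267125033,1
38.32701225903331,0
0.5423927155830444,1
2.3532437952073306,1
23.461667601513327,1
17.19325766464367,1
0.3093824919153316,1
2.3947604670303204,1
16.890065713817325,1
9.22611229396783,1
19.425977875895523,1
7.9217159175391405,1
27.100003991312555,0
13.099502279470334,1
13.320811404042407,1
0.3332161108228742,1
28.210615444894746,0
6.684072038947618,1
19.663014933574157,0
27.124534922753256,1
21.299550812529496,1
19.50733933209627,1
3.6514052930373073,1
18.210071860949864,0
0.544293116664114,1
5.503792050660867,1
4.661364167178803,1
16.309474464898603,0
2.8006956780204546,1
11.314197200987795,1
5.639335088730999,1
12.18904366978088,1
22.84380446394393,0
8.470284171546382,1
5.384323241615969,1
20.226495924309837,1
21.170144266193933,0
21.048435906241913,1
6.129817042295905,1
12.541590665934246,1
3.238386455607206,1
7.648733610025356,1
4.745640859817775,1
14.800637388685876,1
11.475917835039967,1
6.153773676574458,1
15.495255738680118,1
24.64478589315354,1
1.2420590818392891,1
20.71881824210764,1
14.959112952583004,1
3.9196931903872914,1
21.16397649595241,1
6.958818479617738,1
14.955343942245474,0
10.27771975888177,1
31.15568160214935,1
12.524020844426484,1
17.612523620680054,1
10.777532013849298,1
20.286544036915497,1
32.248247470147874,0
3.622646855267908,1
5.200072937555611,1
8.498735666277826,1
26.904276808651293,1
7.990138374518454,1
0.9462468563981178,1
6.612988644323643,1
0.5417237357959376,1
12.256363992008273,1
18.276833768404874,1
10.550264857727575,1
9.426987908458432,1
15.971063948962655,0
3.928235896904573,1
5.908169763453186,1
16.483078712272626,0
1.6688969949188697,1
19.276398638055067,1
2.5615827776558957,1
21.558967876995048,0
17.111156811109087,0
16.023017364584778,1
25.183224658461075,0
3.5452848588177734,1
4.421920588102832,1
10.352477822880138,1
16.425696949155125,1
11.495851047937688,1
2.8935638408033566,1
12.17633083854122,1
2.6281347784052893,1
13.506986675770156,1
26.213911709825844,1
3.35143123133561,1
7.60602428725325,1
27.684365588219492,0
14.463549133570792,1
26.14396956780625,1
12.737613592422475,1
21.69914437827661,0
24.84798212789039,1
20.48672031656297,1
3.2587668009328166,1
12.60232056736876,1
1.7417396827648475,1
12.808833981987496,1
22.64431477325234,0
2.8560006263083206,1
20.698180221088773,1
4.160859976553626,1
21.82327812945594,0
2.024655313974167,1
11.124842589417524,1
3.60330845480881,1
10.261611245190274,1
15.128033455675844,1
21.592878747246232,1
5.187928470162929,1
19.132479071229778,1
7.392925664932909,1
14.294577573106107,1
9.380330564818443,1
23.93469952347537,1
8.712519656318177,1
1.1542807624664242,1
29.196679977687758,0
5.096263874023316,1
1.7601298710635322,1
21.464714740954037,0
0.11746034064070712,1
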