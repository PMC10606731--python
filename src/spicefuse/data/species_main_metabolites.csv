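code,species,metabolite,compound_class,mean_pct,sd_pct
A,Amomum koenigii,Linalool,Monoterpenes,1.9096,0.1795
A,Amomum koenigii,Camphene,Monoterpenes,1.5867,0.5335
A,Amomum koenigii,(-)-Camphor,Monoterpenes,1.1778,0.2981
A,Amomum koenigii,Borneol,Monoterpenes,1.0792,0.4300
A,Amomum koenigii,Limonene,Monoterpenes,1.0783,0.7768
A,Amomum koenigii,alpha-Pinene,Monoterpenes,0.9384,0.1091
B,Amomum kravanh,"1,8-Cineole",Monoterpenes,8.6057,2.3572
B,Amomum kravanh,beta-Selinene,Sesquiterpenes,3.3511,0.2210
B,Amomum kravanh,alpha-Pinene,Monoterpenes,2.6347,0.4049
B,Amomum kravanh,(-)-beta-Pinene,Monoterpenes,2.3827,1.7027
B,Amomum kravanh,Sabinene,Monoterpenes,2.0574,0.2369
B,Amomum kravanh,beta-Myrcene,Monoterpenes,1.6901,1.2053
C,Amomum longiligulare,Borneol,Monoterpenes,1.4594,1.1597
C,Amomum longiligulare,Camphene,Monoterpenes,1.4351,0.3747
C,Amomum longiligulare,beta-Myrcene,Monoterpenes,1.2737,0.9165
C,Amomum longiligulare,Limonene,Monoterpenes,0.9416,1.0558
C,Amomum longiligulare,Linalool,Monoterpenes,0.8842,0.2345
C,Amomum longiligulare,Caryophyllene,Sesquiterpenes,0.8372,0.4591
D,Amomum tsaoko,"1,8-Cineole",Monoterpenes,8.6216,1.8458
D,Amomum tsaoko,gamma-Muurolene,Sesquiterpenes,3.0686,1.3184
D,Amomum tsaoko,Limonene,Monoterpenes,2.4858,1.9670
D,Amomum tsaoko,Linalool,Monoterpenes,2.4640,1.2840
D,Amomum tsaoko,Copaene,Sesquiterpenes,2.2274,0.6573
D,Amomum tsaoko,Geraniol,Monoterpenes,1.5468,1.6610
E,Amomum villosum,Linalool,Monoterpenes,2.0851,0.6833
E,Amomum villosum,(-)-beta-Pinene,Monoterpenes,1.7271,1.2663
E,Amomum villosum,alpha-Pinene,Monoterpenes,1.3186,0.3246
E,Amomum villosum,Borneol,Monoterpenes,0.7760,1.0974
E,Amomum villosum,beta-Myrcene,Monoterpenes,0.7023,0.9932
E,Amomum villosum,Copaene,Monoterpenes,0.6476,0.9159
F,Amomum maximum,(-)-beta-Pinene,Monoterpenes,2.4277,0.1931
F,Amomum maximum,beta-Selinene,Sesquiterpenes,1.4536,0.1007
F,Amomum maximum,Copaene,Sesquiterpenes,1.2216,0.0431
F,Amomum maximum,beta-Bourbonene,Sesquiterpenes,1.2136,0.1201
F,Amomum maximum,alpha-Ocimene,Monoterpenes,1.1048,0.7753
F,Amomum maximum,Humulene,Sesquiterpenes,0.9789,0.6923
G,Amomum paratsaoko,(Z)-2-Decenal,Aldehydes,1.4423,0.5351
G,Amomum paratsaoko,Octanal,Aldehydes,1.1835,0.6240
G,Amomum paratsaoko,(E)-2-Octenal,Aldehydes,1.0320,0.4831
G,Amomum paratsaoko,Limonene,Monoterpenes,0.9243,0.2577
G,Amomum paratsaoko,alpha-Pinene,Monoterpenes,0.8682,0.0838
G,Amomum paratsaoko,alpha-Ocimene,Monoterpenes,0.7899,0.1907
H,Alpinia galanga,Caryophyllene,Sesquiterpenes,2.1802,1.5630
H,Alpinia galanga,Tridecane,Hydrocarbons,1.9142,0.3532
H,Alpinia galanga,Decyl acetate,Esters,1.5508,0.5689
H,Alpinia galanga,Copaene,Sesquiterpenes,1.3953,0.1010
H,Alpinia galanga,Alloaromadendrene,Sesquiterpenes,1.3661,0.0971
H,Alpinia galanga,"1,8-Cineole",Monoterpenes,1.3611,0.4756
I,Alpinia katsumadai,Estragole,Monoterpenes,1.3972,0.3235
I,Alpinia katsumadai,Acetic acid,Acids,0.2495,0.1786
I,Alpinia katsumadai,(-)-beta-Pinene,Monoterpenes,0.2406,0.1470
I,Alpinia katsumadai,o-Cymene,Hydrocarbons,0.2366,0.1923
I,Alpinia katsumadai,"1,8-Cineole",Monoterpenes,0.1577,0.0265
I,Alpinia katsumadai,Limonene,Monoterpenes,0.1514,0.0243
J,Alpinia zerumbet,"1,8-Cineole",Monoterpenes,2.4631,0.9457
J,Alpinia zerumbet,Linalool,Monoterpenes,2.2433,0.2904
J,Alpinia zerumbet,Limonene,Monoterpenes,1.9982,1.1538
J,Alpinia zerumbet,o-Cymene,Hydrocarbons,1.7801,1.2708
J,Alpinia zerumbet,alpha-Pinene,Monoterpenes,1.4746,0.2429
J,Alpinia zerumbet,Borneol,Monoterpenes,1.4343,1.0396
K,Alpinia japonica,"1,8-Cineole",Monoterpenes,1.8123,0.1452
K,Alpinia japonica,Methyl hexanoate,Esters,0.7849,0.1505
K,Alpinia japonica,Linalool,Monoterpenes,0.6186,0.1141
K,Alpinia japonica,o-Cymene,Hydrocarbons,0.5333,0.0981
K,Alpinia japonica,alpha-Terpineol,Monoterpenes,0.4864,0.0370
K,Alpinia japonica,(-)-beta-Pinene,Monoterpenes,0.4055,0.0520
L,Alpinia oxyphylla,Citral,Monoterpenes,3.1651,2.6423
L,Alpinia oxyphylla,Humulene,Sesquiterpenes,1.6426,1.1672
L,Alpinia oxyphylla,(-)-beta-Pinene,Monoterpenes,1.5048,0.7049
L,Alpinia oxyphylla,alpha-Ocimene,Monoterpenes,1.4872,0.8404
L,Alpinia oxyphylla,Linalool,Monoterpenes,1.4704,0.1282
L,Alpinia oxyphylla,beta-Myrcene,Monoterpenes,1.4372,0.1290
M,Zingiber striolatum,Linalool,Monoterpenes,0.6799,0.3538
M,Zingiber striolatum,(-)-Bornyl acetate,Monoterpenes,0.5004,0.0663
M,Zingiber striolatum,Camphene,Monoterpenes,0.3450,0.1443
M,Zingiber striolatum,Acetic acid,Acids,0.2345,0.0430
M,Zingiber striolatum,"1,8-Cineole",Monoterpenes,0.2029,0.0813
M,Zingiber striolatum,Copaene,Sesquiterpenes,0.1585,0.0688
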