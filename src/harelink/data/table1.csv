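genus,species,seeds_fed,germ_temp,control_germ_pct,sgs,fi,ei,mass,volume,density,area,area_mass,origin,neophyte,red_list
Achillea,millefolium,700,15/25,87,4.76,2.12,2.67,0.0002,0.3805,0.0005,5.6116,28058,TK,No,-
Anthriscus,sylvestris,685,15/25,0,,7.11,6.17,0.0037,2.7061,0.0014,23.7055,6372,RH,No,-
Armeria,maritima,800,15/25,7,0.00,2.48,1.99,0.0014,0.6603,0.0021,7.9176,5655,RH,No,V
Arnoseris,minima,800,5/15,81,0.77,1.95,2.15,0.0004,1.7114,0.0002,5.2934,13966,SC,No,2
Artemisia,vulgaris,700,15/25,3,4.76,1.87,2.58,0.0002,0.3565,0.0004,4.4369,27730,TK,No,-
Berteroa,incana,700,15/25,38,0.00,1.83,1.18,0.0005,0.8440,0.0006,6.3010,12911,TK,Yes,-
Brassica,napus,800,15/25,99,0.13,3.70,1.13,0.0033,1.6999,0.0019,10.5926,3209,PP,Yes,-
Bupleurum,rotundifolium,800,5/15,84,0.00,3.59,2.15,0.0025,1.9856,0.0012,14.9075,6011,SC,No,2
Capsella,bursa-pastoris,700,15/25,13,2.20,1.08,1.85,0.0001,0.0902,0.0011,1.6695,16695,TK,No,-
Crepis,capillaris,685,15/25,65,0.22,1.93,3.52,0.0002,0.1633,0.0015,3.3544,13976,RH,No,-
Dactylis,glomerata,800,15/25,75,0.33,5.27,4.77,0.0008,1.9152,0.0004,17.3540,21692,RH,No,-
Daucus,carota,800,15/25,88,0.14,3.70,1.85,0.0012,2.2454,0.0005,14.1852,11890,RH,No,-
Elymus,repens,685,15/25,35,3.34,8.07,4.52,0.0037,4.5846,0.0008,40.2640,10754,RH,No,-
Epilobium,hirsutum,685,15/25,80,0.73,0.93,2.31,0.0001,0.0370,0.0027,1.2335,12335,RH,No,-
Festuca,rubra,800,15/25,88,0.14,6.77,5.85,0.0012,2.2288,0.0005,24.1146,20095,RH,No,-
Legousia,speculumveneris,800,5/15,97,0.00,1.11,1.33,0.0002,0.1727,0.0010,2.3562,14058,SC,No,-
Lithospermum,arvense,800,5/15,96,0.13,5.19,1.58,0.0058,3.7585,0.0015,22.0733,3793,SC,No,V
Lolium,perenne,1500,15/25,87,0.92,6.82,4.32,0.0020,4.1263,0.0005,31.7648,15882,"RH, TK",No,-
Lotus,corniculatus,800,15/25,74,0.51,1.90,1.20,0.0009,0.4686,0.0019,4.0355,4623,RH,No,-
Lupinus,polyphyllus,800,15/25,52,1.44,9.21,1.33,0.0212,25.5254,0.0008,58.9049,2778,SV,Yes,-
Lythrum,salicaria,700,15/25,9,9.52,0.43,2.00,0.0001,0.0048,0.0147,0.3142,4487,TK,No,-
Malva,sylvestris,800,15/25,93,0.13,3.38,1.17,0.0055,11.3008,0.0005,12.3484,2245,RH,No,-
Matricaria,chamomilla,700,15/25,62,2.76,3.19,4.39,0.0001,0.4556,0.0002,7.6111,84568,TK,No,-
Matricaria,discoidea,700,15/25,80,0.18,1.22,2.66,0.0001,0.3247,0.0004,1.8081,12823,TK,Yes,-
Medicago,sativa,800,15/25,95,0.53,3.94,1.72,0.0024,4.3937,0.0005,16.8454,7159,RH,Yes,-
Neslia,paniculata,800,15/25,7,0.00,3.54,1.26,0.0026,9.7147,0.0003,11.4291,4395,SC,No,3
Oenothera,biennis,700,15/25,77,1.11,2.14,1.75,0.0004,0.5551,0.0007,4.7397,11849,TK,Yes,-
Onobrychis,viciifolia,800,15/25,52,0.00,8.26,1.65,0.0178,13.1685,0.0014,39.3092,2208,RH,Yes,-
Papaver,argemone,800,5/15,71,1.76,0.96,1.90,0.0002,0.0546,0.0027,1.2504,8336,SC,No,-
Poa,annua,685,15/25,1,218.98,2.99,3.48,0.0003,0.5983,0.0005,7.8270,26089,RH,No,-
Poa,trivialis,700,15/25,33,4.76,2.78,4.46,0.0001,0.3283,0.0003,5.4201,54200,TK,No,-
Scabiosa,columbaria,800,15/25,11,0.00,7.55,3.05,0.0021,34.1292,0.0001,41.2797,19617,RH,No,-
Silene,latifolia,700,15/25,97,0.29,2.03,1.26,0.0009,0.8296,0.0011,5.7118,6222,TK,No,-
Sorghum,bicolor,800,15/25,100,0.25,9.60,1.31,0.0132,12.1953,0.0011,45.7504,3465,AS,Yes,-
Stellaria,media,700,15/25,27,1.06,1.43,1.11,0.0004,0.3814,0.0010,3.7335,9333,TK,No,-
Taraxacum,officinale,800,15/25,69,0.00,4.00,3.86,0.0007,1.4092,0.0005,12.6786,18112,RH,No,-
Teesdalia,nudicaulis,800,5/15,93,0.13,1.58,1.56,0.0003,0.6136,0.0005,3.9584,13509,SC,No,-
Trifolium,hybridum,800,15/25,99,0.13,1.62,1.16,0.0007,0.4587,0.0015,4.0134,5733,RH,Yes,-
Trifolium,pratense,1500,15/25,74.5,0.54,4.11,1.38,0.0013,4.6064,0.0003,21.0970,16228,"RH, TK",No,-
Trifolium,repens,800,15/25,89,0.70,1.99,1.21,0.0007,0.9920,0.0007,6.2471,8924,RH,No,-
Tripleurospermum,inodorum,685,15/25,30,0.00,2.51,2.55,0.0004,2.5916,0.0001,7.1673,19153,RH,No,-
Valerianella,dentata,800,5/15,83,0.15,2.13,1.84,0.0009,0.6676,0.0013,5.2229,5803,SC,No,V
Valerianella,rimosa,800,5/15,68,2.57,3.54,1.00,0.0012,3.0434,0.0004,12.5664,10385,SC,No,3
Viola,arvensis,700,15/25,46,0.00,2.01,1.75,0.0006,0.4877,0.0012,4.7892,8402,TK,No,-
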