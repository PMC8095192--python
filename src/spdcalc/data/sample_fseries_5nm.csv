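wavelength_nm,F1,F2,F3
380,6.612556167528029,3.197611743163835,2.6024669362029442
385,8.813388425762579,4.16161974051081,3.3509254415175476
390,11.599529609737738,5.366426836241092,4.280143053572881
395,15.068859631962644,6.851820002341107,5.419782505838774
400,22.336532903085597,10.369874066059886,8.28436578876062
405,71.69751261404342,37.62309194262879,31.68471872398735
410,31.874810081637353,14.170165897807383,11.0846612055726
415,37.43179864166805,16.31092673416564,12.630053585966008
420,45.36896301901658,19.674535124415787,15.196598318123598
425,54.208500426254375,23.44424359951704,18.082754387623726
430,65.41698048472325,28.48488103841047,22.04848135974556
435,171.22982820099227,87.14058845778219,72.48580403511082
440,96.43679620989846,43.42231630777499,34.183134497852684
445,95.72520468448016,41.80823900350432,32.41177506599949
450,106.48116803073131,46.87128752106561,36.48268190400878
455,116.79828376713203,51.939731715628845,40.63640561607117
460,126.35360488451629,56.90888126911795,44.806292911993054
465,134.8444233096326,61.679576927872944,48.928658328574606
470,142.0062279789996,66.16329908872213,52.94565345100239
475,147.6314475318904,70.28817239692759,56.80905155926108
480,151.5844003858367,74.00372132971714,60.48322655055381
485,153.81087854157838,77.28385939435069,63.94699285188893
490,154.34133177380056,80.1277765776472,67.19409260142278
495,153.28730097554342,82.55861891089712,70.23226667698069
500,150.8314810975242,84.62009935366417,73.08100673317445
505,147.2124747596513,86.37140675657288,75.7682340039949
510,142.70583504053036,87.88095841038972,78.32626686521921
515,137.60332156899162,89.21964857031604,80.78750791191663
520,132.19237338290773,90.45426883440437,83.18029506276464
525,126.7376388492097,91.64171773510758,85.52532092128364
530,121.4660363777314,92.82448969127577,87.83293912542851
535,116.55633293716684,94.02776981609682,90.10156906912806
540,112.95540098261824,95.72420018048302,92.72120557772298
545,182.25129484657202,138.45346447662322,130.8205287500976
550,117.83635117566769,105.0284400976937,102.79632126387335
555,102.24835697232115,98.92314192829075,98.34363485011875
560,100.0,100.0,100.0
565,98.1620491324095,100.9212003583587,101.40205577492938
570,96.7020398667459,101.6689618060607,102.53457993374475
575,115.59280078327465,113.5745579076991,113.22282545840504
580,104.91372108998894,108.34351099814069,108.94124302512188
585,92.80763911016906,101.94742610954978,103.54027685423586
590,91.45305485994605,101.30851071742066,103.02608577719641
595,89.94794552254699,100.264045360377,102.06189987384177
600,88.22798828057616,98.7979560422104,100.64005378711056
605,86.25696285093393,96.91143856951648,98.76826407143831
610,84.01469142241667,94.61597537945472,96.46353080352978
615,81.4955483759721,91.93237899377364,93.75127405367536
620,78.70656361084247,88.88959644976846,90.66426050285253
625,75.66532532175303,85.52336310353809,87.24138813223118
630,72.39783935968366,81.8747802313745,83.52638899707566
635,68.93645676964391,77.98887702297208,79.56650179067202
640,65.31794254112509,73.91320511333487,75.41115800762488
645,61.58172853640372,69.69650325559262,71.11071837409543
650,57.76837181997103,65.38746109767942,66.71528985677959
655,53.918225021592846,61.03360399423966,62.273647848223575
660,50.07031629102378,56.68031494428965,57.832282848786974
665,46.261431170216945,52.37000469089445,53.434585942299975
670,42.5253858681245,48.14143643824782,49.1201824783275
675,38.89247987075285,44.0292073435022,44.92441859741573
680,35.38911482084864,40.06338485456414,40.87800061142719
685,32.0375657478534,36.26929211549976,37.00678287939502
690,28.8558898580174,32.667433134921524,33.33169583025909
695,25.857957209563317,29.273545324525617,29.868802311677207
700,23.05358679054046,26.09876447853718,26.62946760634045
705,20.44877091018817,23.14988537145802,23.620626339645522
710,18.045970521512714,20.429699956876398,20.84512815082735
715,15.844464194057062,17.93739466867099,18.30214341667692
720,13.840733989827863,15.668988531448713,15.987610465230517
725,12.028872457808088,13.617794617262485,13.894706523973946
730,10.400996312456702,11.77488874989719,12.014326013833857
735,8.947654030318077,10.129571146075863,10.335551609090984
740,7.658216499757594,8.669808774176532,8.846105607760954
745,6.521241897124908,7.382648482933867,7.532771469582926
750,5.524808043714774,6.254593288128361,6.381777758631213
755,4.656807534048333,5.27193649892655,5.379139066103512
760,3.9052028413629833,4.421050527626482,4.510950693928506
765,3.2582403398976063,3.6886291858997278,3.763635878496121
770,2.704623691254057,3.06188397569921,3.1241460732911754
775,2.23364829619259,2.528696301821363,2.5801162567410754
780,1.8352995018559817,2.0777286518797498,2.119978373035739
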