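element,energy_kev,mu_pe_cm2_per_g
H,1,6.8
H,1.11214148,4.88136
H,1.23685867,3.50408
H,1.37556183,2.51539
H,1.52981937,1.80364
H,1.70137558,1.2869
H,1.89217036,0.9182
H,2.10436115,0.652216
H,2.34034732,0.461032
H,2.60279733,0.32589
H,2.89467888,0.230362
H,3.21929245,0.162756
H,3.58030867,0.114961
H,3.98180979,0.0812016
H,4.42833583,0.0573172
H,4.92493597,0.0404569
H,5.47722558,0.0286365
H,6.09144976,0.0202573
H,6.77455395,0.0142369
H,7.53426246,0.0100057
H,8.3791658,0.00702808
H,9.31881786,0.00493293
H,10.3638439,0.00347111
H,11.5260607,0.00245468
H,12.8186102,0.00173588
H,14.2561081,0.00122756
H,15.8548092,0.000865143
H,17.632791,0.000607814
H,19.6101582,0.000427026
H,21.8092704,0.000300602
H,24.2549943,0.000211702
H,26.9749852,0.000149093
H,30,0.000105
H,33.3642444,7.41821e-05
H,37.1057602,5.24094e-05
H,41.266855,3.7087e-05
H,45.8945812,2.63468e-05
H,51.0412675,1.87336e-05
H,56.7651108,1.33697e-05
H,63.1308344,9.54165e-06
H,70.2104196,6.80965e-06
H,78.08392,4.85989e-06
H,86.8403663,3.45893e-06
H,96.5787736,2.45984e-06
H,107.40926,1.74965e-06
H,119.454294,1.24462e-06
H,132.850075,8.85358e-07
H,147.748079,6.298e-07
H,164.316767,4.48799e-07
H,182.743493,3.1991e-07
H,203.236619,2.28573e-07
H,226.027874,1.65482e-07
H,251.374974,1.19806e-07
H,279.564536,8.67372e-08
H,310.915317,6.28483e-08
H,345.781821,4.56135e-08
H,384.558306,3.3105e-08
H,427.683243,2.40266e-08
H,475.644275,1.74378e-08
H,528.983729,1.27261e-08
H,588.304747,9.33318e-09
H,654.278112,6.84484e-09
H,727.649828,5.01992e-09
H,809.249557,3.68155e-09
H,900,2.7e-09
O,1,4550
O,1.11214148,3442.51
O,1.23685867,2604.58
O,1.37556183,1970.61
O,1.52981937,1484.12
O,1.70137558,1095.35
O,1.89217036,808.418
O,2.10436115,597.14
O,2.34034732,441.473
O,2.60279733,326.387
O,2.89467888,241.302
O,3.21929245,175.959
O,3.58030867,127.418
O,3.98180979,92.2683
O,4.42833583,67.0052
O,4.92493597,48.6653
O,5.47722558,35.3016
O,6.09144976,25.574
O,6.77455395,18.404
O,7.53426246,13.2442
O,8.3791658,9.50823
O,9.31881786,6.80494
O,10.3638439,4.87827
O,11.5260607,3.5085
O,12.8186102,2.52335
O,14.2561081,1.81482
O,15.8548092,1.30079
O,17.632791,0.929424
O,19.6101582,0.664083
O,21.8092704,0.47503
O,24.2549943,0.339884
O,26.9749852,0.243187
O,30,0.174
O,33.3642444,0.124293
O,37.1057602,0.0887854
O,41.266855,0.063203
O,45.8945812,0.0446192
O,51.0412675,0.0314909
O,56.7651108,0.0221997
O,63.1308344,0.0157518
O,70.2104196,0.0112561
O,78.08392,0.00804347
O,86.8403663,0.00573095
O,96.5787736,0.00407974
O,107.40926,0.00290516
O,119.454294,0.00206906
O,132.850075,0.00147358
O,147.748079,0.00104949
O,164.316767,0.000753874
O,182.743493,0.000542297
O,203.236619,0.000390788
O,226.027874,0.000284411
O,251.374974,0.000206991
O,279.564536,0.000150645
O,310.915317,0.000109737
O,345.781821,8.0079e-05
O,384.558306,5.84368e-05
O,427.683243,4.27212e-05
O,475.644275,3.12654e-05
O,528.983729,2.29684e-05
O,588.304747,1.69299e-05
O,654.278112,1.2475e-05
O,727.649828,9.19171e-06
O,809.249557,6.79984e-06
O,900,5.2e-06
Fe,1,9050
Fe,1.11514894,6945.05
Fe,1.24355715,5329.69
Fe,1.38675144,4090.05
Fe,1.54643439,3124.52
Fe,1.72450467,2359.17
Fe,1.92307955,1781.3
Fe,2.14452012,1337.49
Fe,2.39145933,1001.11
Fe,2.66683333,749.325
Fe,2.97391635,560.868
Fe,3.31635966,416.869
Fe,3.69823495,309.651
Fe,4.12408278,229.542
Fe,4.59896652,169.27
Fe,5.12853263,124.715
Fe,5.71907772,91.6236
Fe,6.37762344,67.8212
Fe,7.112,50.5
Fe,7.112,398
Fe,7.9011963,306.326
Fe,8.77796723,230.822
Fe,9.75203067,173.435
Fe,10.8341829,129.171
Fe,12.0364181,95.9392
Fe,13.3720616,71.2567
Fe,14.8559173,52.9243
Fe,16.5044317,39.1712
Fe,18.3358767,28.9817
Fe,20.3705513,21.4794
Fe,22.6310074,16.0479
Fe,25.1422992,11.9898
Fe,27.9322611,8.95793
Fe,31.0318164,6.65324
Fe,34.4753196,4.88014
Fe,38.3009375,3.57957
Fe,42.5510722,2.65519
Fe,47.272831,1.98507
Fe,52.5185485,1.47344
Fe,58.3463668,1.08474
Fe,64.8208799,0.79962
Fe,72.0138492,0.589722
Fe,80.0049998,0.43492
Fe,88.8829033,0.319375
Fe,98.7459599,0.234526
Fe,109.703489,0.170612
Fe,121.87694,0.123958
Fe,135.401241,0.0900613
Fe,150.426292,0.0654206
Fe,167.118625,0.0471762
Fe,185.663254,0.0340198
Fe,206.265722,0.0246825
Fe,229.154381,0.0181734
Fe,254.582922,0.0133808
Fe,282.833189,0.00985206
Fe,314.2183,0.0072558
Fe,349.086117,0.00534548
Fe,387.823107,0.00393811
Fe,430.858619,0.00290983
Fe,478.669646,0.00215269
Fe,531.786113,0.00157948
Fe,590.796747,0.00115217
Fe,656.355606,0.000870668
Fe,729.189325,0.000661956
Fe,810.105174,0.000504299
Fe,900,0.00039
Au,1,4600
Au,1.11376364,3952.88
Au,1.24046945,3396.8
Au,1.38158976,2918.94
Au,1.53876444,2490.42
Au,1.71381989,2076.36
Au,1.90879028,1731.14
Au,2.1259412,1576.45
Au,2.36779601,1535.75
Au,2.63716511,1496.1
Au,2.93717861,1457.47
Au,3.27132274,1315.77
Au,3.64348032,1165.95
Au,4.0579759,1024.76
Au,4.51962601,854.091
Au,5.03379511,709.294
Au,5.60645796,558.166
Au,6.24426903,433.432
Au,6.9546398,329.044
Au,7.74582494,249.797
Au,8.62701817,187.145
Au,9.60845916,139.415
Au,10.7015524,104.184
Au,11.919,78
Au,11.919,295
Au,13.2554236,224.887
Au,14.7416943,171.438
Au,16.3946139,130.76
Au,18.2328678,99.7433
Au,20.2772368,75.8586
Au,22.5508317,56.5546
Au,25.0793546,42.163
Au,27.8913892,31.4336
Au,31.0187246,23.4797
Au,34.496714,17.6122
Au,38.3646745,13.2109
Au,42.6663321,9.9967
Au,47.450315,7.60747
Au,52.7707043,5.76354
Au,58.6876448,4.34772
Au,65.2680251,3.31107
Au,72.5862337,2.52792
Au,80.725,1.93
Au,80.725,8.3
Au,89.6478723,6.42504
Au,99.5570271,4.97364
Au,110.561482,3.84084
Au,122.782306,2.96574
Au,136.353948,2.29002
Au,151.425721,1.76889
Au,168.16344,1.37125
Au,186.75125,1.06301
Au,207.393647,0.816177
Au,230.317736,0.615405
Au,255.77572,0.464021
Au,284.047681,0.349877
Au,315.444661,0.265708
Au,350.31208,0.203367
Au,389.033541,0.155653
Au,432.035048,0.120338
Au,479.789691,0.0933725
Au,532.822855,0.0732065
Au,591.717996,0.0577842
Au,657.123065,0.0460692
Au,729.757629,0.0367855
Au,810.420796,0.029447
Au,900,0.024
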