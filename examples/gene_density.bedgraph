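Chr19	0	100000	21.60854601368524
Chr19	100000	200000	21.91722005930774
Chr19	200000	300000	21.033934071311332
Chr19	300000	400000	21.45382865765076
Chr19	400000	500000	21.34008776236724
Chr19	500000	600000	21.815140088754408
Chr19	600000	700000	20.853806782401556
Chr19	700000	800000	21.832190333212296
Chr19	800000	900000	20.85853204823096
Chr19	900000	1000000	20.276805786172297
Chr19	1000000	1100000	20.39223253256655
Chr19	1100000	1200000	21.15077280672061
Chr19	1200000	1300000	21.372697648753856
Chr19	1300000	1400000	21.832576377132987
Chr19	1400000	1500000	22.278307098480887
Chr19	1500000	1600000	21.708116580382363
Chr19	1600000	1700000	21.157334676162783
Chr19	1700000	1800000	20.045895472570265
Chr19	1800000	1900000	20.351682458992187
Chr19	1900000	2000000	19.219067536986927
Chr19	2000000	2100000	19.286635571347716
Chr19	2100000	2200000	19.126679929951397
Chr19	2200000	2300000	18.986013875667325
Chr19	2300000	2400000	17.765961506163748
Chr19	2400000	2500000	17.41249577961621
Chr19	2500000	2600000	17.28173926350591
Chr19	2600000	2700000	16.519013736999963
Chr19	2700000	2800000	16.097853802761904
Chr19	2800000	2900000	15.15946441156769
Chr19	2900000	3000000	15.309634374650772
Chr19	3000000	3100000	14.660790721392274
Chr19	3100000	3200000	13.837998659809907
Chr19	3200000	3300000	13.489281750338632
Chr19	3300000	3400000	13.690244633222989
Chr19	3400000	3500000	13.074618423023885
Chr19	3500000	3600000	11.526570504029788
Chr19	3600000	3700000	11.768617871955934
Chr19	3700000	3800000	10.782640193946447
Chr19	3800000	3900000	10.638778176586781
Chr19	3900000	4000000	10.954810501087026
Chr19	4000000	4100000	11.371158653265606
Chr19	4100000	4200000	10.293808172300967
Chr19	4200000	4300000	9.769768106750986
Chr19	4300000	4400000	9.353680635224332
Chr19	4400000	4500000	7.8447256250499375
Chr19	4500000	4600000	6.578076804682574
Chr19	4600000	4700000	6.15171167922652
Chr19	4700000	4800000	6.761293294211527
Chr19	4800000	4900000	6.118658857108412
Chr19	4900000	5000000	6.453223836315237
Chr19	5000000	5100000	6.408491480235645
Chr19	5100000	5200000	6.19765767086276
Chr19	5200000	5300000	5.1090741461647236
Chr19	5300000	5400000	4.210142067727253
Chr19	5400000	5500000	3.0209126744626156
Chr19	5500000	5600000	3.3329611792211646
Chr19	5600000	5700000	3.7127183418682357
Chr19	5700000	5800000	4.490914639407357
Chr19	5800000	5900000	4.963600263892567
Chr19	5900000	6000000	5.7867790822288985
Chr19	6000000	6100000	5.888932430870694
Chr19	6100000	6200000	5.340038370252474
Chr19	6200000	6300000	5.108602712782135
Chr19	6300000	6400000	5.202034162514886
Chr19	6400000	6500000	5.065849645945892
Chr19	6500000	6600000	4.845591198808181
Chr19	6600000	6700000	5.2008208667061115
Chr19	6700000	6800000	5.146256865643463
Chr19	6800000	6900000	4.821070748364974
Chr19	6900000	7000000	4.665698537628166
Chr19	7000000	7100000	5.697813532543648
Chr19	7100000	7200000	6.004066160837072
Chr19	7200000	7300000	6.681119569051581
Chr19	7300000	7400000	6.5224010257114795
Chr19	7400000	7500000	7.340942974392058
Chr19	7500000	7600000	7.777773296837596
Chr19	7600000	7700000	8.221527049911879
Chr19	7700000	7800000	8.678127638586172
Chr19	7800000	7900000	10.492683867839215
Chr19	7900000	8000000	11.436820207927465
Chr19	8000000	8100000	11.964364274293517
Chr19	8100000	8200000	13.017448863323368
Chr19	8200000	8300000	13.600857229147044
Chr19	8300000	8400000	14.534934074836137
Chr19	8400000	8500000	14.681991375076427
Chr19	8500000	8600000	14.803400947397837
Chr19	8600000	8700000	14.860498130595289
Chr19	8700000	8800000	15.201814228571461
Chr19	8800000	8900000	13.930683746888757
Chr19	8900000	9000000	14.355243451684412
Chr19	9000000	9100000	14.774380693631384
Chr19	9100000	9200000	15.66263204495299
Chr19	9200000	9300000	16.81059978765544
Chr19	9300000	9400000	18.18447572704737
Chr19	9400000	9500000	19.235981958503825
Chr19	9500000	9600000	19.34728140273065
Chr19	9600000	9700000	19.068589768741635
Chr19	9700000	9800000	18.545037911620906
Chr19	9800000	9900000	18.935263577570623
Chr19	9900000	10000000	19.02617839463108
Chr19	10000000	10100000	19.086027912249502
Chr19	10100000	10200000	20.340265501104426
Chr19	10200000	10300000	20.479253493340625
Chr19	10300000	10400000	21.300618945575003
Chr19	10400000	10500000	21.384892225517465
Chr19	10500000	10600000	22.451672650416413
Chr19	10600000	10700000	21.71898140200116
Chr19	10700000	10800000	21.70541831531042
Chr19	10800000	10900000	21.681610765157764
Chr19	10900000	11000000	21.713460654695247
Chr19	11000000	11100000	21.712562988031642
Chr19	11100000	11200000	21.76192303294444
Chr19	11200000	11300000	22.16907237580908
Chr19	11300000	11400000	22.131417080500682
Chr19	11400000	11500000	22.186425046009752
Chr19	11500000	11600000	21.49475863164005
Chr19	11600000	11700000	21.918774149571817
Chr19	11700000	11800000	22.16840785645253
Chr19	11800000	11900000	23.040905704720593
Chr19	11900000	12000000	22.664929097339343
Chr19	12000000	12100000	23.42430787257538
Chr19	12100000	12200000	22.94193599994206
Chr19	12200000	12300000	22.649558274885166
Chr19	12300000	12400000	21.241140099590137
Chr19	12400000	12500000	21.987489632688842
Chr19	12500000	12600000	21.36360954820434
Chr19	12600000	12700000	22.333926224219667
Chr19	12700000	12800000	22.305494376237732
Chr19	12800000	12900000	23.01824546055178
Chr19	12900000	13000000	23.049194960468995
Chr19	13000000	13100000	22.688328733053133
Chr19	13100000	13200000	21.306458041301592
Chr19	13200000	13300000	21.292201116742238
Chr19	13300000	13400000	21.396452049035464
Chr19	13400000	13500000	20.854056565382145
Chr19	13500000	13600000	22.086162439834695
Chr19	13600000	13700000	23.312429262991134
Chr19	13700000	13800000	23.82582166823935
Chr19	13800000	13900000	24.05095192557907
Chr19	13900000	14000000	24.375503323560473
Chr19	14000000	14100000	24.096128992254375
Chr19	14100000	14200000	23.699071720098903
Chr19	14200000	14300000	23.643173850168935
Chr19	14300000	14400000	23.178524888942018
Chr19	14400000	14500000	22.797389371702778
Chr19	14500000	14600000	22.95132918362799
Chr19	14600000	14700000	22.38881423661969
Chr19	14700000	14800000	22.2895997368226
Chr19	14800000	14900000	22.568917277453416
Chr19	14900000	15000000	23.322052464412504
Chr19	15000000	15100000	22.175450026137064
Chr19	15100000	15200000	22.430884168877775
Chr19	15200000	15300000	22.394274545991045
Chr19	15300000	15400000	22.75924341170136
Chr19	15400000	15500000	22.786745771997047
Chr19	15500000	15600000	24.369709244739052
Chr19	15600000	15700000	24.59996024425201
Chr19	15700000	15800000	24.44761369476617
Chr19	15800000	15900000	24.46421394391866
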