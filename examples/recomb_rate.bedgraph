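Chr19	0	100000	3.558995331135308
Chr19	100000	200000	3.688193432463658
Chr19	200000	300000	3.522704621153526
Chr19	300000	400000	3.434880854913742
Chr19	400000	500000	3.4017688411407643
Chr19	500000	600000	3.3274725559191736
Chr19	600000	700000	3.3357837975410423
Chr19	700000	800000	3.4287920802034235
Chr19	800000	900000	3.3179331929466884
Chr19	900000	1000000	3.331856004544176
Chr19	1000000	1100000	3.323131094869359
Chr19	1100000	1200000	3.3231859262918775
Chr19	1200000	1300000	3.2611229803786728
Chr19	1300000	1400000	3.4297813006845024
Chr19	1400000	1500000	3.451840955837805
Chr19	1500000	1600000	3.5670991421611054
Chr19	1600000	1700000	3.427455465075148
Chr19	1700000	1800000	3.450485981692067
Chr19	1800000	1900000	3.17064662929767
Chr19	1900000	2000000	3.136024609549492
Chr19	2000000	2100000	2.965496382494943
Chr19	2100000	2200000	2.99548866940377
Chr19	2200000	2300000	3.079956134779021
Chr19	2300000	2400000	3.1341988421871156
Chr19	2400000	2500000	2.928162555102408
Chr19	2500000	2600000	2.9680918308985804
Chr19	2600000	2700000	2.962144066489161
Chr19	2700000	2800000	2.606380798402003
Chr19	2800000	2900000	2.711343891850214
Chr19	2900000	3000000	2.661202803969518
Chr19	3000000	3100000	2.3979164528886554
Chr19	3100000	3200000	2.2668910953077765
Chr19	3200000	3300000	2.4334371417502383
Chr19	3300000	3400000	2.325976916643961
Chr19	3400000	3500000	2.3146407119934698
Chr19	3500000	3600000	2.343166382263835
Chr19	3600000	3700000	2.1749361469684336
Chr19	3700000	3800000	2.0361782726699875
Chr19	3800000	3900000	1.7580440179842673
Chr19	3900000	4000000	1.69295214286764
Chr19	4000000	4100000	1.7645027862795055
Chr19	4100000	4200000	1.7482838974191117
Chr19	4200000	4300000	1.7778058982590437
Chr19	4300000	4400000	1.7231958829796477
Chr19	4400000	4500000	1.7613503184977106
Chr19	4500000	4600000	1.4456866527187942
Chr19	4600000	4700000	1.4626745181841572
Chr19	4700000	4800000	1.1500541068223333
Chr19	4800000	4900000	1.0721431633301668
Chr19	4900000	5000000	1.0209954545008235
Chr19	5000000	5100000	1.1672058523522109
Chr19	5100000	5200000	1.0606799328234116
Chr19	5200000	5300000	1.163391621713968
Chr19	5300000	5400000	1.2595019708290796
Chr19	5400000	5500000	1.208029086728285
Chr19	5500000	5600000	1.152801368218665
Chr19	5600000	5700000	1.2481938544775157
Chr19	5700000	5800000	1.078544617443291
Chr19	5800000	5900000	0.9329223301338014
Chr19	5900000	6000000	0.8354430499662975
Chr19	6000000	6100000	0.8861598795717553
Chr19	6100000	6200000	0.7116879584419482
Chr19	6200000	6300000	0.8988192431110513
Chr19	6300000	6400000	0.9755621458463224
Chr19	6400000	6500000	0.984637477350305
Chr19	6500000	6600000	0.8701897173850837
Chr19	6600000	6700000	1.0384514084377467
Chr19	6700000	6800000	1.1228053507910465
Chr19	6800000	6900000	1.2487251607557641
Chr19	6900000	7000000	1.2441703839382898
Chr19	7000000	7100000	1.3464462239838892
Chr19	7100000	7200000	1.118811701573272
Chr19	7200000	7300000	1.0580963081295804
Chr19	7300000	7400000	1.0535960372431545
Chr19	7400000	7500000	1.2779313111115331
Chr19	7500000	7600000	1.412753021710745
Chr19	7600000	7700000	1.625944287412337
Chr19	7700000	7800000	1.5819089351352997
Chr19	7800000	7900000	1.6223009454378852
Chr19	7900000	8000000	1.8613767418069809
Chr19	8000000	8100000	1.7640174500522126
Chr19	8100000	8200000	1.8711630769906777
Chr19	8200000	8300000	2.186665352406983
Chr19	8300000	8400000	2.2589013877317923
Chr19	8400000	8500000	2.1543187670544537
Chr19	8500000	8600000	2.3859370082574034
Chr19	8600000	8700000	2.553998148849349
Chr19	8700000	8800000	2.55083763592889
Chr19	8800000	8900000	2.6506616749391956
Chr19	8900000	9000000	2.6140843928572814
Chr19	9000000	9100000	2.5805700898939263
Chr19	9100000	9200000	2.5499465445496385
Chr19	9200000	9300000	2.5166976093629865
Chr19	9300000	9400000	2.563368133987228
Chr19	9400000	9500000	2.6310812748091186
Chr19	9500000	9600000	2.7272231898427632
Chr19	9600000	9700000	2.837616605407441
Chr19	9700000	9800000	2.944941330784891
Chr19	9800000	9900000	3.1241135089722625
Chr19	9900000	10000000	3.2999393229631604
Chr19	10000000	10100000	3.2969694729564534
Chr19	10100000	10200000	3.2968117291220724
Chr19	10200000	10300000	3.3678660031041137
Chr19	10300000	10400000	3.3895983566165926
Chr19	10400000	10500000	3.3356502376452
Chr19	10500000	10600000	3.52143351573087
Chr19	10600000	10700000	3.6112563953075627
Chr19	10700000	10800000	3.5857213559202976
Chr19	10800000	10900000	3.5298812081274766
Chr19	10900000	11000000	3.5826711219856002
Chr19	11000000	11100000	3.413001954819004
Chr19	11100000	11200000	3.345019210031147
Chr19	11200000	11300000	3.3407681993843306
Chr19	11300000	11400000	3.2809024360614014
Chr19	11400000	11500000	3.2997286436888142
Chr19	11500000	11600000	3.4037959459470053
Chr19	11600000	11700000	3.4997932874915376
Chr19	11700000	11800000	3.5063073208414437
Chr19	11800000	11900000	3.481628014719594
Chr19	11900000	12000000	3.440739666077722
Chr19	12000000	12100000	3.420950225724511
Chr19	12100000	12200000	3.41805077911846
Chr19	12200000	12300000	3.628755611329044
Chr19	12300000	12400000	3.545332879434283
Chr19	12400000	12500000	3.635095194696019
Chr19	12500000	12600000	3.760488926779077
Chr19	12600000	12700000	3.721295523041084
Chr19	12700000	12800000	3.624947218681314
Chr19	12800000	12900000	3.846881249090814
Chr19	12900000	13000000	3.8212594697329965
Chr19	13000000	13100000	3.7221025597453283
Chr19	13100000	13200000	3.6957264685898163
Chr19	13200000	13300000	3.73838853125107
Chr19	13300000	13400000	3.7130596385132812
Chr19	13400000	13500000	3.753772368458866
Chr19	13500000	13600000	3.739111004791247
Chr19	13600000	13700000	3.84032056868119
Chr19	13700000	13800000	3.7493532197549424
Chr19	13800000	13900000	3.7817902019945904
Chr19	13900000	14000000	3.7215935797681605
Chr19	14000000	14100000	3.6965637068119634
Chr19	14100000	14200000	3.6976161548708593
Chr19	14200000	14300000	3.616830891379513
Chr19	14300000	14400000	3.5012757098290828
Chr19	14400000	14500000	3.6186734114950356
Chr19	14500000	14600000	3.6003460734511763
Chr19	14600000	14700000	3.4714219530536017
Chr19	14700000	14800000	3.4769713838002296
Chr19	14800000	14900000	3.541895818304544
Chr19	14900000	15000000	3.2958277294567857
Chr19	15000000	15100000	3.3560026184547938
Chr19	15100000	15200000	3.3677578960085572
Chr19	15200000	15300000	3.3694544381320104
Chr19	15300000	15400000	3.537144942683576
Chr19	15400000	15500000	3.677732842554111
Chr19	15500000	15600000	3.5987540924757333
Chr19	15600000	15700000	3.6255154985778217
Chr19	15700000	15800000	3.6683811434860285
Chr19	15800000	15900000	3.4629086104877755
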