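Chr19	0	100000	0.06410430452017013
Chr19	100000	200000	0.03407955650171576
Chr19	200000	300000	0.03470833290448582
Chr19	300000	400000	0.04603657316243615
Chr19	400000	500000	0.035453140808450606
Chr19	500000	600000	0.03334214101639642
Chr19	600000	700000	0.039991246348553895
Chr19	700000	800000	0.04148514761546882
Chr19	800000	900000	0.05181766914621113
Chr19	900000	1000000	0.05035842099481641
Chr19	1000000	1100000	0.052026055521623316
Chr19	1100000	1200000	0.0549188620124406
Chr19	1200000	1300000	0.04424642542957913
Chr19	1300000	1400000	0.04670243597079883
Chr19	1400000	1500000	0.04513162100413791
Chr19	1500000	1600000	0.03405566469701709
Chr19	1600000	1700000	0.020232565158037126
Chr19	1700000	1800000	0.04883503644356156
Chr19	1800000	1900000	0.045426803132340016
Chr19	1900000	2000000	0.07214626698904544
Chr19	2000000	2100000	0.08148438975753321
Chr19	2100000	2200000	0.10199895624176764
Chr19	2200000	2300000	0.10736654764408025
Chr19	2300000	2400000	0.11816245981823612
Chr19	2400000	2500000	0.11378520896770268
Chr19	2500000	2600000	0.12127147069747703
Chr19	2600000	2700000	0.12499076970792053
Chr19	2700000	2800000	0.12385173312536021
Chr19	2800000	2900000	0.12155350921474706
Chr19	2900000	3000000	0.11743653175892647
Chr19	3000000	3100000	0.12292802775816147
Chr19	3100000	3200000	0.12378352719528385
Chr19	3200000	3300000	0.1330068981897872
Chr19	3300000	3400000	0.1622176551035401
Chr19	3400000	3500000	0.1833085046090813
Chr19	3500000	3600000	0.20865395601558298
Chr19	3600000	3700000	0.22168027676133348
Chr19	3700000	3800000	0.22416601152153265
Chr19	3800000	3900000	0.246057574812236
Chr19	3900000	4000000	0.2477050832726927
Chr19	4000000	4100000	0.24269176614232757
Chr19	4100000	4200000	0.2585017150821178
Chr19	4200000	4300000	0.29503591279234165
Chr19	4300000	4400000	0.276047872084224
Chr19	4400000	4500000	0.29669852391218593
Chr19	4500000	4600000	0.3186944045847251
Chr19	4600000	4700000	0.32153883711017694
Chr19	4700000	4800000	0.3222141546958571
Chr19	4800000	4900000	0.3461171018401523
Chr19	4900000	5000000	0.37395612904633424
Chr19	5000000	5100000	0.3810002936920835
Chr19	5100000	5200000	0.41685084473967643
Chr19	5200000	5300000	0.42691904844607637
Chr19	5300000	5400000	0.43342454616895715
Chr19	5400000	5500000	0.43213398875216047
Chr19	5500000	5600000	0.4377752461809952
Chr19	5600000	5700000	0.4293188504147548
Chr19	5700000	5800000	0.43803174136332884
Chr19	5800000	5900000	0.439056585062351
Chr19	5900000	6000000	0.43766378857475974
Chr19	6000000	6100000	0.44567592222664515
Chr19	6100000	6200000	0.44535040596508046
Chr19	6200000	6300000	0.43535616735838073
Chr19	6300000	6400000	0.4325246397393665
Chr19	6400000	6500000	0.42044815983640915
Chr19	6500000	6600000	0.4172009495367969
Chr19	6600000	6700000	0.43178260110416605
Chr19	6700000	6800000	0.4276128903342481
Chr19	6800000	6900000	0.4140559146635291
Chr19	6900000	7000000	0.4084755627292872
Chr19	7000000	7100000	0.39730988997642913
Chr19	7100000	7200000	0.3639022925904178
Chr19	7200000	7300000	0.35451153765012466
Chr19	7300000	7400000	0.3521606658862677
Chr19	7400000	7500000	0.35913792312096404
Chr19	7500000	7600000	0.34542832551924674
Chr19	7600000	7700000	0.3282179493760391
Chr19	7700000	7800000	0.3002636937994259
Chr19	7800000	7900000	0.2979271766566804
Chr19	7900000	8000000	0.2534616284577579
Chr19	8000000	8100000	0.23899111475338503
Chr19	8100000	8200000	0.22861036405664656
Chr19	8200000	8300000	0.21881508860050874
Chr19	8300000	8400000	0.19465699879489748
Chr19	8400000	8500000	0.20831421038725806
Chr19	8500000	8600000	0.1943653469757627
Chr19	8600000	8700000	0.19279578073513598
Chr19	8700000	8800000	0.1905569166712464
Chr19	8800000	8900000	0.19054571998621736
Chr19	8900000	9000000	0.16631133528705871
Chr19	9000000	9100000	0.1738204968172167
Chr19	9100000	9200000	0.15132014350457645
Chr19	9200000	9300000	0.14878052871325279
Chr19	9300000	9400000	0.13464989823218607
Chr19	9400000	9500000	0.12877954363655153
Chr19	9500000	9600000	0.1051891165448559
Chr19	9600000	9700000	0.11306287663255012
Chr19	9700000	9800000	0.0991654688311258
Chr19	9800000	9900000	0.07831627437040035
Chr19	9900000	10000000	0.07195366799793412
Chr19	10000000	10100000	0.07836478762014791
Chr19	10100000	10200000	0.06818089787888121
Chr19	10200000	10300000	0.0629746562874083
Chr19	10300000	10400000	0.062224111649354985
Chr19	10400000	10500000	0.07161842301567631
Chr19	10500000	10600000	0.06651188564663248
Chr19	10600000	10700000	0.06283622047368007
Chr19	10700000	10800000	0.05573368432135108
Chr19	10800000	10900000	0.06364094405839793
Chr19	10900000	11000000	0.056763766054415944
Chr19	11000000	11100000	0.05666012261103479
Chr19	11100000	11200000	0.045880179682525654
Chr19	11200000	11300000	0.04309335646969722
Chr19	11300000	11400000	0.029976353518446092
Chr19	11400000	11500000	0.026339382978880378
Chr19	11500000	11600000	0.012346268850083199
Chr19	11600000	11700000	0.02892141591418956
Chr19	11700000	11800000	0.03315119821618215
Chr19	11800000	11900000	0.03859887234997484
Chr19	11900000	12000000	0.026914443629152626
Chr19	12000000	12100000	0.03616150778437176
Chr19	12100000	12200000	0.012493815936782393
Chr19	12200000	12300000	0.015794905669639252
Chr19	12300000	12400000	0.033095251347922905
Chr19	12400000	12500000	0.06167987579254841
Chr19	12500000	12600000	0.06597668744245135
Chr19	12600000	12700000	0.07765733318943828
Chr19	12700000	12800000	0.0857926431194791
Chr19	12800000	12900000	0.06557333543402949
Chr19	12900000	13000000	0.05910810228247
Chr19	13000000	13100000	0.057481880480678586
Chr19	13100000	13200000	0.07483040354071821
Chr19	13200000	13300000	0.06410045017132217
Chr19	13300000	13400000	0.07680361971435834
Chr19	13400000	13500000	0.0664165778148562
Chr19	13500000	13600000	0.06602352934883651
Chr19	13600000	13700000	0.06305735558398269
Chr19	13700000	13800000	0.06844196303938475
Chr19	13800000	13900000	0.07893041731191802
Chr19	13900000	14000000	0.08539448193615536
Chr19	14000000	14100000	0.07950826867241392
Chr19	14100000	14200000	0.07011694925017921
Chr19	14200000	14300000	0.06423417431710489
Chr19	14300000	14400000	0.05477469673063067
Chr19	14400000	14500000	0.04451899193952098
Chr19	14500000	14600000	0.03688281545662184
Chr19	14600000	14700000	0.04696240798112712
Chr19	14700000	14800000	0.044182265931966676
Chr19	14800000	14900000	0.02774526370055184
Chr19	14900000	15000000	0.039224592805191694
Chr19	15000000	15100000	0.041184210936777994
Chr19	15100000	15200000	0.024397124778640516
Chr19	15200000	15300000	0.028973359020543068
Chr19	15300000	15400000	0.03127649405703743
Chr19	15400000	15500000	0.024244555252397722
Chr19	15500000	15600000	0.020799418327043264
Chr19	15600000	15700000	0.029245039727871666
Chr19	15700000	15800000	0.017907709216602306
Chr19	15800000	15900000	0.015077860762023464
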