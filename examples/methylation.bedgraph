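Chr19	0	100000	8.364363067615407
Chr19	100000	200000	8.22769038831734
Chr19	200000	300000	9.881112860321176
Chr19	300000	400000	8.872604138359216
Chr19	400000	500000	8.869902085846611
Chr19	500000	600000	8.80006013701027
Chr19	600000	700000	8.715379269625245
Chr19	700000	800000	8.485210796773789
Chr19	800000	900000	9.584908723836616
Chr19	900000	1000000	9.181250462691011
Chr19	1000000	1100000	9.240875943568089
Chr19	1100000	1200000	9.462587280824424
Chr19	1200000	1300000	9.521026767000361
Chr19	1300000	1400000	8.864681815862308
Chr19	1400000	1500000	8.137083857857654
Chr19	1500000	1600000	8.483091705883474
Chr19	1600000	1700000	8.399304361901567
Chr19	1700000	1800000	7.964802068531598
Chr19	1800000	1900000	8.1665540238174
Chr19	1900000	2000000	8.971220059318924
Chr19	2000000	2100000	9.302584736207141
Chr19	2100000	2200000	9.563214478933276
Chr19	2200000	2300000	10.096560886723916
Chr19	2300000	2400000	10.443997116702317
Chr19	2400000	2500000	10.370533134005273
Chr19	2500000	2600000	9.186292332340397
Chr19	2600000	2700000	9.356626817751412
Chr19	2700000	2800000	8.606018711942742
Chr19	2800000	2900000	8.155519009576782
Chr19	2900000	3000000	8.780957073380819
Chr19	3000000	3100000	9.72960334102531
Chr19	3100000	3200000	10.99587314710914
Chr19	3200000	3300000	12.50318627807696
Chr19	3300000	3400000	13.745270506407849
Chr19	3400000	3500000	13.912722404402519
Chr19	3500000	3600000	14.469402393222511
Chr19	3600000	3700000	14.173635315164734
Chr19	3700000	3800000	13.78603575264377
Chr19	3800000	3900000	14.884003328446422
Chr19	3900000	4000000	16.385997919115574
Chr19	4000000	4100000	17.296620263827464
Chr19	4100000	4200000	19.07758345456736
Chr19	4200000	4300000	22.435882809756038
Chr19	4300000	4400000	25.079258095303633
Chr19	4400000	4500000	26.502127481801256
Chr19	4500000	4600000	28.16325709334084
Chr19	4600000	4700000	28.83439616203156
Chr19	4700000	4800000	28.710047659090243
Chr19	4800000	4900000	29.088012948852487
Chr19	4900000	5000000	29.876138076360157
Chr19	5000000	5100000	30.79224639668987
Chr19	5100000	5200000	31.955159845743513
Chr19	5200000	5300000	33.93267670209205
Chr19	5300000	5400000	34.97927746484649
Chr19	5400000	5500000	35.51111161050257
Chr19	5500000	5600000	36.98037559307992
Chr19	5600000	5700000	37.98895374822516
Chr19	5700000	5800000	37.80294351326634
Chr19	5800000	5900000	36.96319271547447
Chr19	5900000	6000000	36.90807517310295
Chr19	6000000	6100000	36.39944789474416
Chr19	6100000	6200000	37.364932923140685
Chr19	6200000	6300000	37.23692038252139
Chr19	6300000	6400000	36.82203221811294
Chr19	6400000	6500000	36.85578486135069
Chr19	6500000	6600000	36.052722125415556
Chr19	6600000	6700000	33.50990443095203
Chr19	6700000	6800000	32.61242734002465
Chr19	6800000	6900000	32.317305221867926
Chr19	6900000	7000000	32.39608210983801
Chr19	7000000	7100000	30.753632105793702
Chr19	7100000	7200000	29.556889283609742
Chr19	7200000	7300000	27.830321503773746
Chr19	7300000	7400000	26.60713131047249
Chr19	7400000	7500000	24.629890890697343
Chr19	7500000	7600000	24.61993439712386
Chr19	7600000	7700000	24.04824118562847
Chr19	7700000	7800000	23.387820273925954
Chr19	7800000	7900000	22.02342479485119
Chr19	7900000	8000000	20.571455768777394
Chr19	8000000	8100000	19.483604011478924
Chr19	8100000	8200000	17.9024853788321
Chr19	8200000	8300000	16.759834433423787
Chr19	8300000	8400000	15.805975818220658
Chr19	8400000	8500000	15.231400891756888
Chr19	8500000	8600000	13.839118710170906
Chr19	8600000	8700000	13.20372974508115
Chr19	8700000	8800000	12.666861741123105
Chr19	8800000	8900000	12.202061723170509
Chr19	8900000	9000000	11.33500595810423
Chr19	9000000	9100000	11.554358218687321
Chr19	9100000	9200000	11.930690822674972
Chr19	9200000	9300000	12.730962575522817
Chr19	9300000	9400000	12.514860039985301
Chr19	9400000	9500000	12.364813529147098
Chr19	9500000	9600000	11.363537676827685
Chr19	9600000	9700000	11.131789637240516
Chr19	9700000	9800000	9.421242732421085
Chr19	9800000	9900000	9.03625250979571
Chr19	9900000	10000000	8.199342491365075
Chr19	10000000	10100000	7.67577999971858
Chr19	10100000	10200000	6.890615681285239
Chr19	10200000	10300000	6.815123890096814
Chr19	10300000	10400000	7.893646939388512
Chr19	10400000	10500000	8.564588789948816
Chr19	10500000	10600000	9.375727733054752
Chr19	10600000	10700000	9.925570619591678
Chr19	10700000	10800000	9.967874548003019
Chr19	10800000	10900000	9.048599673580227
Chr19	10900000	11000000	8.88582207174163
Chr19	11000000	11100000	8.465145326402157
Chr19	11100000	11200000	7.6347268634706715
Chr19	11200000	11300000	8.362579991049484
Chr19	11300000	11400000	8.54248324155377
Chr19	11400000	11500000	8.202524594145926
Chr19	11500000	11600000	8.148121107388022
Chr19	11600000	11700000	9.344782092541095
Chr19	11700000	11800000	9.087542118917415
Chr19	11800000	11900000	9.598993607002107
Chr19	11900000	12000000	8.537750030650757
Chr19	12000000	12100000	9.321222013028503
Chr19	12100000	12200000	9.723863696618816
Chr19	12200000	12300000	9.045602801557566
Chr19	12300000	12400000	8.02522990525763
Chr19	12400000	12500000	8.61695297976737
Chr19	12500000	12600000	7.370835499398298
Chr19	12600000	12700000	5.605788291548069
Chr19	12700000	12800000	6.113762719625418
Chr19	12800000	12900000	5.856102387076172
Chr19	12900000	13000000	6.061015873369488
Chr19	13000000	13100000	6.891367756295873
Chr19	13100000	13200000	7.552220860719366
Chr19	13200000	13300000	7.985698990794872
Chr19	13300000	13400000	8.762866650840756
Chr19	13400000	13500000	8.545812817740051
Chr19	13500000	13600000	8.122986993699168
Chr19	13600000	13700000	7.744879410809548
Chr19	13700000	13800000	7.3711534561045156
Chr19	13800000	13900000	6.200289878622321
Chr19	13900000	14000000	6.985259257602748
Chr19	14000000	14100000	7.762494252614424
Chr19	14100000	14200000	7.501989149831585
Chr19	14200000	14300000	7.673384448056538
Chr19	14300000	14400000	9.445511740066586
Chr19	14400000	14500000	8.74822694501409
Chr19	14500000	14600000	8.116090463124664
Chr19	14600000	14700000	8.303373602256805
Chr19	14700000	14800000	7.795366350132463
Chr19	14800000	14900000	6.690637859133611
Chr19	14900000	15000000	7.421485990946346
Chr19	15000000	15100000	7.86292895031708
Chr19	15100000	15200000	8.550271967159597
Chr19	15200000	15300000	8.927603413868418
Chr19	15300000	15400000	9.677244523215688
Chr19	15400000	15500000	10.022837870409242
Chr19	15500000	15600000	9.53254260899351
Chr19	15600000	15700000	8.73092183521944
Chr19	15700000	15800000	8.012038066364408
Chr19	15800000	15900000	7.237322648310849
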