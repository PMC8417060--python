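Chr19	0	100000	0.043601698020867684
Chr19	100000	200000	0.04324630967866618
Chr19	200000	300000	0.040830136445536805
Chr19	300000	400000	0.04087026023661604
Chr19	400000	500000	0.042612914273894666
Chr19	500000	600000	0.04327725191727877
Chr19	600000	700000	0.04314250344976125
Chr19	700000	800000	0.04244919769040801
Chr19	800000	900000	0.04115121926856733
Chr19	900000	1000000	0.04035658528560265
Chr19	1000000	1100000	0.039070339437352906
Chr19	1100000	1200000	0.03853503942142175
Chr19	1200000	1300000	0.03894564997076916
Chr19	1300000	1400000	0.03661296437957993
Chr19	1400000	1500000	0.037546329920944366
Chr19	1500000	1600000	0.040420559377337156
Chr19	1600000	1700000	0.04148141901800325
Chr19	1700000	1800000	0.04211941948993555
Chr19	1800000	1900000	0.04196224182019133
Chr19	1900000	2000000	0.039166982958608584
Chr19	2000000	2100000	0.038362253446249744
Chr19	2100000	2200000	0.03917425039578853
Chr19	2200000	2300000	0.03896030255557754
Chr19	2300000	2400000	0.040058725346013006
Chr19	2400000	2500000	0.040937736392560264
Chr19	2500000	2600000	0.0436698870406927
Chr19	2600000	2700000	0.046003860687164555
Chr19	2700000	2800000	0.04405634468731444
Chr19	2800000	2900000	0.046083965880636464
Chr19	2900000	3000000	0.04566884714732941
Chr19	3000000	3100000	0.042684643661257626
Chr19	3100000	3200000	0.04069100703716977
Chr19	3200000	3300000	0.04033135502768342
Chr19	3300000	3400000	0.04007398093931787
Chr19	3400000	3500000	0.03777623962395133
Chr19	3500000	3600000	0.03752048796302487
Chr19	3600000	3700000	0.03539722134224641
Chr19	3700000	3800000	0.03286000860786294
Chr19	3800000	3900000	0.03087077636239243
Chr19	3900000	4000000	0.029563879007470466
Chr19	4000000	4100000	0.02802416276355857
Chr19	4100000	4200000	0.028009572909314228
Chr19	4200000	4300000	0.02698418273550838
Chr19	4300000	4400000	0.024812807738153614
Chr19	4400000	4500000	0.02160424015662302
Chr19	4500000	4600000	0.022077991223049428
Chr19	4600000	4700000	0.022820004999684965
Chr19	4700000	4800000	0.023467071163728533
Chr19	4800000	4900000	0.01987758242969663
Chr19	4900000	5000000	0.02284441120015167
Chr19	5000000	5100000	0.02191259633117922
Chr19	5100000	5200000	0.02159945432226909
Chr19	5200000	5300000	0.024838386813841973
Chr19	5300000	5400000	0.025430360973964276
Chr19	5400000	5500000	0.023871065800578482
Chr19	5500000	5600000	0.023464592034733552
Chr19	5600000	5700000	0.020114116721912406
Chr19	5700000	5800000	0.021012774352411508
Chr19	5800000	5900000	0.02065202916817797
Chr19	5900000	6000000	0.020852380258907115
Chr19	6000000	6100000	0.01958680525162109
Chr19	6100000	6200000	0.017754591100688243
Chr19	6200000	6300000	0.01623575551996069
Chr19	6300000	6400000	0.018993422452712974
Chr19	6400000	6500000	0.01842542506501678
Chr19	6500000	6600000	0.017851492272353515
Chr19	6600000	6700000	0.01778860244175739
Chr19	6700000	6800000	0.01767824773584387
Chr19	6800000	6900000	0.017718876381485938
Chr19	6900000	7000000	0.017162128002736313
Chr19	7000000	7100000	0.017699141294060455
Chr19	7100000	7200000	0.017523379005382946
Chr19	7200000	7300000	0.016931711427267928
Chr19	7300000	7400000	0.018068587701424766
Chr19	7400000	7500000	0.019947517404547404
Chr19	7500000	7600000	0.021210241439860708
Chr19	7600000	7700000	0.023612805835906567
Chr19	7700000	7800000	0.024467958145469662
Chr19	7800000	7900000	0.025617079666420135
Chr19	7900000	8000000	0.02472379130085258
Chr19	8000000	8100000	0.027398661153963284
Chr19	8100000	8200000	0.027591555913123768
Chr19	8200000	8300000	0.025912088388189487
Chr19	8300000	8400000	0.026497267971048215
Chr19	8400000	8500000	0.026478062463324698
Chr19	8500000	8600000	0.02638739482914547
Chr19	8600000	8700000	0.028157391752603216
Chr19	8700000	8800000	0.029892101308788624
Chr19	8800000	8900000	0.029647226393663274
Chr19	8900000	9000000	0.03060667641325438
Chr19	9000000	9100000	0.03308474327817226
Chr19	9100000	9200000	0.03245287645561587
Chr19	9200000	9300000	0.03349506222444996
Chr19	9300000	9400000	0.03269361141941416
Chr19	9400000	9500000	0.034901450027564826
Chr19	9500000	9600000	0.034465520917184356
Chr19	9600000	9700000	0.03585089348308844
Chr19	9700000	9800000	0.03608190707176473
Chr19	9800000	9900000	0.035196472622343586
Chr19	9900000	10000000	0.038323821539065495
Chr19	10000000	10100000	0.03857736652846323
Chr19	10100000	10200000	0.03822938931865838
Chr19	10200000	10300000	0.03850276203826556
Chr19	10300000	10400000	0.040021040157899965
Chr19	10400000	10500000	0.04040350939870603
Chr19	10500000	10600000	0.0386516014031621
Chr19	10600000	10700000	0.03737512127465845
Chr19	10700000	10800000	0.036512845796383545
Chr19	10800000	10900000	0.039001763420165605
Chr19	10900000	11000000	0.0396835202897189
Chr19	11000000	11100000	0.038391590740024045
Chr19	11100000	11200000	0.03859859648998794
Chr19	11200000	11300000	0.0394839275933437
Chr19	11300000	11400000	0.04127673328737068
Chr19	11400000	11500000	0.04118823935535469
Chr19	11500000	11600000	0.042219405179204035
Chr19	11600000	11700000	0.04034105305335136
Chr19	11700000	11800000	0.04053731271729699
Chr19	11800000	11900000	0.04026799868209639
Chr19	11900000	12000000	0.040114610102473906
Chr19	12000000	12100000	0.04129101654110054
Chr19	12100000	12200000	0.04255070195193016
Chr19	12200000	12300000	0.04180643007792634
Chr19	12300000	12400000	0.040406076787583144
Chr19	12400000	12500000	0.03867309432280765
Chr19	12500000	12600000	0.04054747558762479
Chr19	12600000	12700000	0.040176125223971154
Chr19	12700000	12800000	0.041250608867014586
Chr19	12800000	12900000	0.042353423625103685
Chr19	12900000	13000000	0.041981296719223
Chr19	13000000	13100000	0.040398227382755024
Chr19	13100000	13200000	0.043330472905224106
Chr19	13200000	13300000	0.045061588298679206
Chr19	13300000	13400000	0.047425474518691675
Chr19	13400000	13500000	0.04711214991964671
Chr19	13500000	13600000	0.04685096018383888
Chr19	13600000	13700000	0.046669885434123676
Chr19	13700000	13800000	0.05011944091031514
Chr19	13800000	13900000	0.05017043957553031
Chr19	13900000	14000000	0.05055010604394621
Chr19	14000000	14100000	0.04990747963724582
Chr19	14100000	14200000	0.04992115770658169
Chr19	14200000	14300000	0.050582311066943206
Chr19	14300000	14400000	0.04985653022093186
Chr19	14400000	14500000	0.05024203296253942
Chr19	14500000	14600000	0.05237560109866554
Chr19	14600000	14700000	0.05103978004143626
Chr19	14700000	14800000	0.04764977588382758
Chr19	14800000	14900000	0.045263459287859
Chr19	14900000	15000000	0.04454209423288668
Chr19	15000000	15100000	0.045765661441283946
Chr19	15100000	15200000	0.04811708020437181
Chr19	15200000	15300000	0.04708493123581371
Chr19	15300000	15400000	0.04691727555141011
Chr19	15400000	15500000	0.048304350768566574
Chr19	15500000	15600000	0.047970822179677255
Chr19	15600000	15700000	0.048436077726848784
Chr19	15700000	15800000	0.04533672466691789
Chr19	15800000	15900000	0.04466321821089564
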