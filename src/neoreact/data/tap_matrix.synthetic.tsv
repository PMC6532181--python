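position	residue	weight
1	A	0.2274
1	R	0.4777
1	N	-0.4688
1	D	-0.1522
1	C	0.4443
1	Q	0.4626
1	E	-0.216
1	G	0.9135
1	H	0.091
1	I	0.5982
1	L	-0.2805
1	K	-0.328
1	M	0.3573
1	F	-0.017
1	P	0.2801
1	S	-0.1522
1	T	0.1156
1	W	-0.4286
1	Y	-1.1373
1	V	-0.2575
2	A	0.3022
2	R	0.2473
2	N	0.034
2	D	-0.4161
2	C	0.3007
2	Q	0.5446
2	E	-0.1496
2	G	-0.28
2	H	0.1818
2	I	-0.5449
2	L	1.0055
2	K	0.1493
2	M	0.5897
2	F	-0.4707
2	P	-0.1939
2	S	0.6635
2	T	-0.0007
2	W	0.2706
2	Y	0.3334
2	V	-0.8907
3	A	0.667
3	R	-0.4093
3	N	-0.3532
3	D	0.3581
3	C	-0.3345
3	Q	1.0652
3	E	-0.1375
3	G	-0.7685
3	H	-0.4212
3	I	0.2751
3	L	0.5505
3	K	-0.058
3	M	-0.2223
3	F	0.1368
3	P	0.4998
3	S	0.6651
3	T	-0.2298
3	W	-0.4797
3	Y	-0.1711
3	V	-1.2543
4	A	-0.0358
4	R	0.0247
4	N	-0.2437
4	D	0.2214
4	C	0.0129
4	Q	-0.0746
4	E	-0.0258
4	G	-0.0568
4	H	0.0848
4	I	-0.023
4	L	0.0361
4	K	-0.0231
4	M	0.0887
4	F	-0.0718
4	P	0.1525
4	S	-0.0477
4	T	0.0332
4	W	0.1407
4	Y	-0.0648
4	V	0.0386
5	A	-0.0631
5	R	0.2896
5	N	0.3029
5	D	0.0266
5	C	0.1028
5	Q	-0.116
5	E	0.1125
5	G	0.0226
5	H	-0.1023
5	I	-0.0249
5	L	0.0959
5	K	-0.2016
5	M	0.0432
5	F	0.1627
5	P	-0.0243
5	S	0.1543
5	T	0.0041
5	W	0.0322
5	Y	-0.2224
5	V	-0.1898
6	A	-0.0073
6	R	-0.195
6	N	0.0734
6	D	0.0965
6	C	0.2759
6	Q	0.0331
6	E	0.2364
6	G	0.0084
6	H	-0.2429
6	I	0.0098
6	L	-0.2392
6	K	0.023
6	M	-0.089
6	F	-0.2103
6	P	0.1848
6	S	0.1349
6	T	-0.0782
6	W	-0.0478
6	Y	-0.0253
6	V	-0.1954
7	A	-0.1738
7	R	0.0228
7	N	0.176
7	D	-0.128
7	C	0.1587
7	Q	0.0939
7	E	-0.137
7	G	-0.1321
7	H	-0.0389
7	I	0.2569
7	L	0.0027
7	K	0.0215
7	M	0.2263
7	F	0.0908
7	P	0.161
7	S	-0.1751
7	T	-0.1352
7	W	0.3197
7	Y	0.2684
7	V	0.0058
8	A	0.0016
8	R	-0.1655
8	N	0.2078
8	D	0.2161
8	C	-0.1337
8	Q	0.1287
8	E	0.0582
8	G	-0.0515
8	H	-0.1648
8	I	0.1589
8	L	0.1306
8	K	-0.1319
8	M	0.1338
8	F	0.155
8	P	-0.3626
8	S	-0.3247
8	T	0.2644
8	W	-0.0577
8	Y	0.0118
8	V	0.1481
9	A	0.6444
9	R	-0.843
9	N	-1.3638
9	D	-1.5955
9	C	0.8785
9	Q	-1.5294
9	E	-1.1122
9	G	-0.0498
9	H	-1.5612
9	I	1.6995
9	L	1.5515
9	K	-0.3316
9	M	0.7533
9	F	1.3695
9	P	-1.3182
9	S	-0.1886
9	T	-0.5784
9	W	-0.7979
9	Y	-0.2828
9	V	1.2942
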