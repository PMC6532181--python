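offset	residue	weight
bias	*	-1.5
-2	A	-0.3428
-2	R	-0.1517
-2	N	0.0957
-2	D	-0.0591
-2	C	0.2005
-2	Q	-0.002
-2	E	0.0646
-2	G	-0.0342
-2	H	0.1159
-2	I	-0.1444
-2	L	0.3684
-2	K	0.4104
-2	M	0.2627
-2	F	0.2371
-2	P	0.3105
-2	S	0.3029
-2	T	0.216
-2	W	0.1516
-2	Y	0.0454
-2	V	0.0003
-1	A	0.8868
-1	R	-2.1307
-1	N	-1.6498
-1	D	-1.6451
-1	C	1.3038
-1	Q	-1.7873
-1	E	-1.5297
-1	G	-0.2175
-1	H	-1.3511
-1	I	2.3695
-1	L	1.558
-1	K	-1.8445
-1	M	1.0761
-1	F	1.2472
-1	P	-0.7408
-1	S	-0.0211
-1	T	-0.4325
-1	W	-0.2881
-1	Y	-0.4244
-1	V	2.0042
1	A	0.438
1	R	0.0519
1	N	0.049
1	D	0.2264
1	C	-0.1832
1	Q	0.0783
1	E	-0.0259
1	G	0.2571
1	H	0.11
1	I	-0.1367
1	L	-0.1373
1	K	0.5561
1	M	0.309
1	F	0.0166
1	P	0.5733
1	S	-0.0854
1	T	-0.2829
1	W	0.2534
1	Y	0.04
1	V	0.0448
2	A	-0.1236
2	R	0.0587
2	N	0.2966
2	D	0.0925
2	C	-0.3072
2	Q	0.3481
2	E	0.1499
2	G	-0.2392
2	H	0.0458
2	I	-0.1106
2	L	-0.1554
2	K	-0.261
2	M	0.1886
2	F	0.341
2	P	0.0201
2	S	-0.0009
2	T	0.0862
2	W	0.0779
2	Y	-0.1299
2	V	-0.3202
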