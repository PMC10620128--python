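position	rna	dna	activity
1	A	A	0.6
1	A	C	0.7
1	A	G	0.55
1	C	A	0.65
1	C	C	0.4
1	C	T	0.6
1	G	A	0.7
1	G	G	0.45
1	G	T	0.9
1	U	C	0.55
1	U	G	0.85
1	U	T	0.5
2	A	A	0.5938
2	A	C	0.6928
2	A	G	0.5444
2	C	A	0.6433
2	C	C	0.3959
2	C	T	0.5938
2	G	A	0.6928
2	G	G	0.4454
2	G	T	0.8908
2	U	C	0.5444
2	U	G	0.8413
2	U	T	0.4949
3	A	A	0.5826
3	A	C	0.6797
3	A	G	0.534
3	C	A	0.6311
3	C	C	0.3884
3	C	T	0.5826
3	G	A	0.6797
3	G	G	0.4369
3	G	T	0.8739
3	U	C	0.534
3	U	G	0.8253
3	U	T	0.4855
4	A	A	0.568
4	A	C	0.6627
4	A	G	0.5207
4	C	A	0.6153
4	C	C	0.3787
4	C	T	0.568
4	G	A	0.6627
4	G	G	0.426
4	G	T	0.852
4	U	C	0.5207
4	U	G	0.8047
4	U	T	0.4733
5	A	A	0.5507
5	A	C	0.6425
5	A	G	0.5048
5	C	A	0.5966
5	C	C	0.3672
5	C	T	0.5507
5	G	A	0.6425
5	G	G	0.4131
5	G	T	0.8261
5	U	C	0.5048
5	U	G	0.7802
5	U	T	0.4589
6	A	A	0.5312
6	A	C	0.6197
6	A	G	0.4869
6	C	A	0.5754
6	C	C	0.3541
6	C	T	0.5312
6	G	A	0.6197
6	G	G	0.3984
6	G	T	0.7967
6	U	C	0.4869
6	U	G	0.7525
6	U	T	0.4426
7	A	A	0.5095
7	A	C	0.5944
7	A	G	0.467
7	C	A	0.552
7	C	C	0.3397
7	C	T	0.5095
7	G	A	0.5944
7	G	G	0.3821
7	G	T	0.7642
7	U	C	0.467
7	U	G	0.7218
7	U	T	0.4246
8	A	A	0.486
8	A	C	0.5669
8	A	G	0.4455
8	C	A	0.5264
8	C	C	0.324
8	C	T	0.486
8	G	A	0.5669
8	G	G	0.3645
8	G	T	0.7289
8	U	C	0.4455
8	U	G	0.6884
8	U	T	0.405
9	A	A	0.4607
9	A	C	0.5374
9	A	G	0.4223
9	C	A	0.499
9	C	C	0.3071
9	C	T	0.4607
9	G	A	0.5374
9	G	G	0.3455
9	G	T	0.691
9	U	C	0.4223
9	U	G	0.6526
9	U	T	0.3839
10	A	A	0.4337
10	A	C	0.506
10	A	G	0.3976
10	C	A	0.4699
10	C	C	0.2892
10	C	T	0.4337
10	G	A	0.506
10	G	G	0.3253
10	G	T	0.6506
10	U	C	0.3976
10	U	G	0.6145
10	U	T	0.3614
11	A	A	0.4053
11	A	C	0.4728
11	A	G	0.3715
11	C	A	0.439
11	C	C	0.2702
11	C	T	0.4053
11	G	A	0.4728
11	G	G	0.304
11	G	T	0.6079
11	U	C	0.3715
11	U	G	0.5741
11	U	T	0.3377
12	A	A	0.3753
12	A	C	0.4379
12	A	G	0.3441
12	C	A	0.4066
12	C	C	0.2502
12	C	T	0.3753
12	G	A	0.4379
12	G	G	0.2815
12	G	T	0.563
12	U	C	0.3441
12	U	G	0.5317
12	U	T	0.3128
13	A	A	0.344
13	A	C	0.4014
13	A	G	0.3153
13	C	A	0.3727
13	C	C	0.2293
13	C	T	0.344
13	G	A	0.4014
13	G	G	0.258
13	G	T	0.516
13	U	C	0.3153
13	U	G	0.4874
13	U	T	0.2867
14	A	A	0.3114
14	A	C	0.3633
14	A	G	0.2854
14	C	A	0.3373
14	C	C	0.2076
14	C	T	0.3114
14	G	A	0.3633
14	G	G	0.2335
14	G	T	0.467
14	U	C	0.2854
14	U	G	0.4411
14	U	T	0.2595
15	A	A	0.2774
15	A	C	0.3237
15	A	G	0.2543
15	C	A	0.3005
15	C	C	0.1849
15	C	T	0.2774
15	G	A	0.3237
15	G	G	0.2081
15	G	T	0.4161
15	U	C	0.2543
15	U	G	0.393
15	U	T	0.2312
16	A	A	0.2423
16	A	C	0.2826
16	A	G	0.2221
16	C	A	0.2624
16	C	C	0.1615
16	C	T	0.2423
16	G	A	0.2826
16	G	G	0.1817
16	G	T	0.3634
16	U	C	0.2221
16	U	G	0.3432
16	U	T	0.2019
17	A	A	0.2059
17	A	C	0.2402
17	A	G	0.1887
17	C	A	0.223
17	C	C	0.1373
17	C	T	0.2059
17	G	A	0.2402
17	G	G	0.1544
17	G	T	0.3088
17	U	C	0.1887
17	U	G	0.2917
17	U	T	0.1716
18	A	A	0.1684
18	A	C	0.1964
18	A	G	0.1543
18	C	A	0.1824
18	C	C	0.1122
18	C	T	0.1684
18	G	A	0.1964
18	G	G	0.1263
18	G	T	0.2526
18	U	C	0.1543
18	U	G	0.2385
18	U	T	0.1403
19	A	A	0.1297
19	A	C	0.1514
19	A	G	0.1189
19	C	A	0.1405
19	C	C	0.0865
19	C	T	0.1297
19	G	A	0.1514
19	G	G	0.0973
19	G	T	0.1946
19	U	C	0.1189
19	U	G	0.1838
19	U	T	0.1081
20	A	A	0.09
20	A	C	0.105
20	A	G	0.0825
20	C	A	0.0975
20	C	C	0.06
20	C	T	0.09
20	G	A	0.105
20	G	G	0.0675
20	G	T	0.135
20	U	C	0.0825
20	U	G	0.1275
20	U	T	0.075
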