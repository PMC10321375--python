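# SYNTHETIC CFD mismatch penalties: position	guide_base	genome_base	penalty
#source	synthetic-cfd-shape-v1 (generated by scripts/make_default_tables.py; not the published empirical table)
# position 1 = 5' (PAM-distal for 3'-PAM models); penalties shrink toward
# the 3' end; transition mismatches are milder than transversions.
1	A	C	0.7391
1	A	G	0.9500
1	A	T	0.7495
1	C	A	0.6773
1	C	G	0.7318
1	C	T	0.9500
1	G	A	0.9500
1	G	C	0.7469
1	G	T	0.7005
1	T	A	0.7219
1	T	C	0.9500
1	T	G	0.7574
2	A	C	0.7166
2	A	G	0.9500
2	A	T	0.7444
2	C	A	0.7446
2	C	G	0.6840
2	C	T	0.9500
2	G	A	0.9500
2	G	C	0.6800
2	G	T	0.6565
2	T	A	0.7004
2	T	C	0.9500
2	T	G	0.7455
3	A	C	0.7091
3	A	G	0.9500
3	A	T	0.7009
3	C	A	0.6596
3	C	G	0.7004
3	C	T	0.9500
3	G	A	0.9500
3	G	C	0.6887
3	G	T	0.7202
3	T	A	0.7326
3	T	C	0.9500
3	T	G	0.7249
4	A	C	0.7010
4	A	G	0.9496
4	A	T	0.7022
4	C	A	0.6319
4	C	G	0.6409
4	C	T	0.9500
4	G	A	0.9500
4	G	C	0.7186
4	G	T	0.6938
4	T	A	0.7132
4	T	C	0.9500
4	T	G	0.6717
5	A	C	0.6332
5	A	G	0.9441
5	A	T	0.6745
5	C	A	0.6704
5	C	G	0.6543
5	C	T	0.9465
5	G	A	0.9500
5	G	C	0.6963
5	G	T	0.6480
5	T	A	0.6449
5	T	C	0.9186
5	T	G	0.6465
6	A	C	0.6453
6	A	G	0.9500
6	A	T	0.6059
6	C	A	0.6266
6	C	G	0.6412
6	C	T	0.9105
6	G	A	0.9500
6	G	C	0.6341
6	G	T	0.6068
6	T	A	0.5968
6	T	C	0.9264
6	T	G	0.6313
7	A	C	0.6168
7	A	G	0.9363
7	A	T	0.5848
7	C	A	0.6243
7	C	G	0.6082
7	C	T	0.9302
7	G	A	0.8930
7	G	C	0.6363
7	G	T	0.6087
7	T	A	0.6275
7	T	C	0.9303
7	T	G	0.5901
8	A	C	0.5886
8	A	G	0.8896
8	A	T	0.6052
8	C	A	0.5949
8	C	G	0.5706
8	C	T	0.8951
8	G	A	0.8481
8	G	C	0.6211
8	G	T	0.6357
8	T	A	0.6121
8	T	C	0.8760
8	T	G	0.6534
9	A	C	0.6385
9	A	G	0.8764
9	A	T	0.5803
9	C	A	0.6122
9	C	G	0.5537
9	C	T	0.8830
9	G	A	0.8467
9	G	C	0.6317
9	G	T	0.6349
9	T	A	0.5864
9	T	C	0.8614
9	T	G	0.5497
10	A	C	0.5537
10	A	G	0.8141
10	A	T	0.6232
10	C	A	0.5933
10	C	G	0.5535
10	C	T	0.8759
10	G	A	0.8622
10	G	C	0.6157
10	G	T	0.5834
10	T	A	0.5891
10	T	C	0.8344
10	T	G	0.5616
11	A	C	0.5878
11	A	G	0.8561
11	A	T	0.5345
11	C	A	0.5906
11	C	G	0.5249
11	C	T	0.7914
11	G	A	0.8441
11	G	C	0.5180
11	G	T	0.5853
11	T	A	0.5631
11	T	C	0.8568
11	T	G	0.5347
12	A	C	0.5112
12	A	G	0.7599
12	A	T	0.5802
12	C	A	0.5033
12	C	G	0.5300
12	C	T	0.7957
12	G	A	0.7785
12	G	C	0.5671
12	G	T	0.5167
12	T	A	0.5296
12	T	C	0.8165
12	T	G	0.5114
13	A	C	0.4998
13	A	G	0.8137
13	A	T	0.5619
13	C	A	0.5313
13	C	G	0.5403
13	C	T	0.7284
13	G	A	0.7652
13	G	C	0.5010
13	G	T	0.4971
13	T	A	0.5413
13	T	C	0.7685
13	T	G	0.5200
14	A	C	0.4750
14	A	G	0.7139
14	A	T	0.4686
14	C	A	0.5310
14	C	G	0.4801
14	C	T	0.7134
14	G	A	0.7769
14	G	C	0.5601
14	G	T	0.5279
14	T	A	0.5124
14	T	C	0.7382
14	T	G	0.5467
15	A	C	0.4692
15	A	G	0.6811
15	A	T	0.5398
15	C	A	0.4897
15	C	G	0.4718
15	C	T	0.7666
15	G	A	0.7145
15	G	C	0.4788
15	G	T	0.4508
15	T	A	0.4684
15	T	C	0.7289
15	T	G	0.5151
16	A	C	0.4623
16	A	G	0.7451
16	A	T	0.4867
16	C	A	0.5189
16	C	G	0.4406
16	C	T	0.6811
16	G	A	0.7325
16	G	C	0.5196
16	G	T	0.4932
16	T	A	0.5268
16	T	C	0.6785
16	T	G	0.4368
17	A	C	0.4879
17	A	G	0.7210
17	A	T	0.4704
17	C	A	0.4594
17	C	G	0.4262
17	C	T	0.6627
17	G	A	0.6876
17	G	C	0.4861
17	G	T	0.4717
17	T	A	0.4384
17	T	C	0.6965
17	T	G	0.5133
18	A	C	0.4263
18	A	G	0.6694
18	A	T	0.4722
18	C	A	0.4522
18	C	G	0.4466
18	C	T	0.7084
18	G	A	0.6882
18	G	C	0.4678
18	G	T	0.4358
18	T	A	0.4401
18	T	C	0.6258
18	T	G	0.4011
19	A	C	0.4124
19	A	G	0.6229
19	A	T	0.4603
19	C	A	0.4039
19	C	G	0.4293
19	C	T	0.6207
19	G	A	0.6853
19	G	C	0.4819
19	G	T	0.4240
19	T	A	0.3981
19	T	C	0.6810
19	T	G	0.4772
20	A	C	0.4525
20	A	G	0.5633
20	A	T	0.3803
20	C	A	0.3898
20	C	G	0.4453
20	C	T	0.6118
20	G	A	0.6612
20	G	C	0.4560
20	G	T	0.4430
20	T	A	0.4530
20	T	C	0.5628
20	T	G	0.4042
21	A	C	0.4016
21	A	G	0.5490
21	A	T	0.3952
21	C	A	0.4475
21	C	G	0.3684
21	C	T	0.6296
21	G	A	0.5706
21	G	C	0.4404
21	G	T	0.3721
21	T	A	0.4302
21	T	C	0.6053
21	T	G	0.3860
22	A	C	0.3798
22	A	G	0.5682
22	A	T	0.3391
22	C	A	0.3467
22	C	G	0.3860
22	C	T	0.5466
22	G	A	0.5449
22	G	C	0.3583
22	G	T	0.4242
22	T	A	0.3688
22	T	C	0.5710
22	T	G	0.3607
23	A	C	0.3646
23	A	G	0.4937
23	A	T	0.4042
23	C	A	0.3442
23	C	G	0.3363
23	C	T	0.5495
23	G	A	0.5848
23	G	C	0.3356
23	G	T	0.3284
23	T	A	0.3992
23	T	C	0.5901
23	T	G	0.3612
24	A	C	0.3481
24	A	G	0.4797
24	A	T	0.3693
24	C	A	0.3233
24	C	G	0.3451
24	C	T	0.5480
24	G	A	0.4804
24	G	C	0.3591
24	G	T	0.3265
24	T	A	0.3988
24	T	C	0.4904
24	T	G	0.3549
25	A	C	0.3139
25	A	G	0.4481
25	A	T	0.3712
25	C	A	0.3435
25	C	G	0.3135
25	C	T	0.4676
25	G	A	0.5172
25	G	C	0.3011
25	G	T	0.3495
25	T	A	0.3161
25	T	C	0.4903
25	T	G	0.2980
26	A	C	0.3570
26	A	G	0.4826
26	A	T	0.2975
26	C	A	0.3072
26	C	G	0.3051
26	C	T	0.5138
26	G	A	0.5044
26	G	C	0.2954
26	G	T	0.3352
26	T	A	0.2796
26	T	C	0.4371
26	T	G	0.3099
27	A	C	0.2881
27	A	G	0.4835
27	A	T	0.3440
27	C	A	0.3503
27	C	G	0.2916
27	C	T	0.4520
27	G	A	0.4787
27	G	C	0.3087
27	G	T	0.2645
27	T	A	0.3293
27	T	C	0.4637
27	T	G	0.3137
28	A	C	0.3220
28	A	G	0.3825
28	A	T	0.2726
28	C	A	0.2726
28	C	G	0.2604
28	C	T	0.4170
28	G	A	0.3930
28	G	C	0.3360
28	G	T	0.2459
28	T	A	0.2796
28	T	C	0.4340
28	T	G	0.3356
29	A	C	0.2980
29	A	G	0.3606
29	A	T	0.2973
29	C	A	0.3000
29	C	G	0.2328
29	C	T	0.4291
29	G	A	0.3741
29	G	C	0.2631
29	G	T	0.2925
29	T	A	0.2244
29	T	C	0.4458
29	T	G	0.2673
30	A	C	0.2731
30	A	G	0.3820
30	A	T	0.2672
30	C	A	0.2137
30	C	G	0.2654
30	C	T	0.3658
30	G	A	0.3479
30	G	C	0.2142
30	G	T	0.2728
30	T	A	0.2493
30	T	C	0.4148
30	T	G	0.2381
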