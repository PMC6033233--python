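# SYNTHETIC stand-in for the published CFD per-position mismatch
# penalty table. Keys: protospacer position (1 = PAM-distal),
# guide RNA base, DNA base on the strand the guide hybridises to
# (Watson-Crick pairs are matches and score 1 implicitly). Values
# are seeded plausible placeholders in [0,1], NOT the published
# measurements; substitute a transcription for real CFD scores.
position	guide_rna	dna	penalty
1	A	G	0.844034
1	A	C	0.389013
1	A	A	0.459331
1	C	T	0.65785
1	C	C	0.486441
1	C	A	0.45954
1	G	T	0.419389
1	G	G	0.662977
1	G	A	0.665788
1	U	T	0.651203
1	U	G	0.525028
1	U	C	0.777532
2	A	G	0.343127
2	A	C	0.331169
2	A	A	0.343956
2	C	T	0.890344
2	C	C	0.279772
2	C	A	0.261092
2	G	T	0.847612
2	G	G	0.939452
2	G	A	0.883772
2	U	T	0.57129
2	U	G	0.606435
2	U	C	0.538702
3	A	G	0.317808
3	A	C	0.320087
3	A	A	0.647263
3	C	T	0.66423
3	C	C	0.599706
3	C	A	0.491968
3	G	T	0.516664
3	G	G	0.619056
3	G	A	0.253541
3	U	T	0.378656
3	U	G	0.331087
3	U	C	0.763645
4	A	G	0.404859
4	A	C	0.334993
4	A	A	0.264789
4	C	T	0.537557
4	C	C	0.46225
4	C	A	0.694696
4	G	T	0.549286
4	G	G	0.699677
4	G	A	0.579735
4	U	T	0.730105
4	U	G	0.457246
4	U	C	0.313451
5	A	G	0.75958
5	A	C	0.347837
5	A	A	0.790461
5	C	T	0.512661
5	C	C	0.332891
5	C	A	0.437483
5	G	T	0.226199
5	G	G	0.579489
5	G	A	0.356138
5	U	T	0.771646
5	U	G	0.602244
5	U	C	0.684568
6	A	G	0.321567
6	A	C	0.680581
6	A	A	0.486491
6	C	T	0.725539
6	C	C	0.264255
6	C	A	0.633168
6	G	T	0.404096
6	G	G	0.363582
6	G	A	0.526277
6	U	T	0.583506
6	U	G	0.662191
6	U	C	0.763656
7	A	G	0.632106
7	A	C	0.483803
7	A	A	0.225669
7	C	T	0.53664
7	C	C	0.218914
7	C	A	0.496204
7	G	T	0.378607
7	G	G	0.320225
7	G	A	0.635037
7	U	T	0.445052
7	U	G	0.723785
7	U	C	0.375511
8	A	G	0.60846
8	A	C	0.202471
8	A	A	0.493138
8	C	T	0.414018
8	C	C	0.280884
8	C	A	0.302498
8	G	T	0.29266
8	G	G	0.64946
8	G	A	0.457444
8	U	T	0.416058
8	U	G	0.262779
8	U	C	0.565539
9	A	G	0.51571
9	A	C	0.228769
9	A	A	0.505501
9	C	T	0.517457
9	C	C	0.633206
9	C	A	0.503235
9	G	T	0.191404
9	G	G	0.559144
9	G	A	0.564128
9	U	T	0.447519
9	U	G	0.57782
9	U	C	0.342733
10	A	G	0.402925
10	A	C	0.322605
10	A	A	0.156644
10	C	T	0.203149
10	C	C	0.503732
10	C	A	0.154154
10	G	T	0.373684
10	G	G	0.513443
10	G	A	0.355272
10	U	T	0.563629
10	U	G	0.26472
10	U	C	0.389518
11	A	G	0.311521
11	A	C	0.375198
11	A	A	0.294801
11	C	T	0.310507
11	C	C	0.335375
11	C	A	0.435689
11	G	T	0.460797
11	G	G	0.237921
11	G	A	0.257315
11	U	T	0.164566
11	U	G	0.300083
11	U	C	0.285718
12	A	G	0.302355
12	A	C	0.202452
12	A	A	0.379652
12	C	T	0.367658
12	C	C	0.464434
12	C	A	0.390035
12	G	T	0.141882
12	G	G	0.413756
12	G	A	0.402077
12	U	T	0.267791
12	U	G	0.381452
12	U	C	0.303372
13	A	G	0.413412
13	A	C	0.137362
13	A	A	0.215561
13	C	T	0.234848
13	C	C	0.143189
13	C	A	0.243376
13	G	T	0.23125
13	G	G	0.410801
13	G	A	0.193544
13	U	T	0.202142
13	U	G	0.431386
13	U	C	0.432689
14	A	G	0.208255
14	A	C	0.358101
14	A	A	0.194107
14	C	T	0.14055
14	C	C	0.223445
14	C	A	0.224008
14	G	T	0.391738
14	G	G	0.25752
14	G	A	0.269927
14	U	T	0.105
14	U	G	0.324669
14	U	C	0.197813
15	A	G	0.283486
15	A	C	0.361742
15	A	A	0.314468
15	C	T	0.207627
15	C	C	0.1476
15	C	A	0.207625
15	G	T	0.174868
15	G	G	0.223075
15	G	A	0.217806
15	U	T	0.313964
15	U	G	0.164552
15	U	C	0.155293
16	A	G	0.171794
16	A	C	0.290365
16	A	A	0.285059
16	C	T	0.152354
16	C	C	0.118515
16	C	A	0.316656
16	G	T	0.301924
16	G	G	0.200247
16	G	A	0.089211
16	U	T	0.239155
16	U	G	0.089164
16	U	C	0.214668
17	A	G	0.185327
17	A	C	0.081448
17	A	A	0.20467
17	C	T	0.234815
17	C	C	0.192629
17	C	A	0.084773
17	G	T	0.152484
17	G	G	0.230407
17	G	A	0.128389
17	U	T	0.204758
17	U	G	0.110697
17	U	C	0.07076
18	A	G	0.148057
18	A	C	0.121385
18	A	A	0.107165
18	C	T	0.170558
18	C	C	0.091139
18	C	A	0.14127
18	G	T	0.062705
18	G	G	0.1679
18	G	A	0.193453
18	U	T	0.179116
18	U	G	0.090146
18	U	C	0.08373
19	A	G	0.144924
19	A	C	0.165561
19	A	A	0.053338
19	C	T	0.052012
19	C	C	0.080166
19	C	A	0.075199
19	G	T	0.07814
19	G	G	0.070055
19	G	A	0.055085
19	U	T	0.157996
19	U	G	0.1171
19	U	C	0.187007
20	A	G	0.120484
20	A	C	0.138953
20	A	A	0.12626
20	C	T	0.107665
20	C	C	0.135861
20	C	A	0.086221
20	G	T	0.097329
20	G	G	0.049914
20	G	A	0.039086
20	U	T	0.091719
20	U	G	0.079594
20	U	C	0.096186
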