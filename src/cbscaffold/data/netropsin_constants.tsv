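# Synthetic netropsin binding constants (1/uM), strand-symmetric.
# AT-content graded with central-AT bonus and deterministic scatter;
# stand-in defaults, replace with a measured table for real data.
# 4mer	K_per_uM
AAAA	104.478
AAAC	30.3611
AAAG	23.3451
AAAT	140.174
AACA	12.9984
AACC	2.67736
AACG	3.49454
AACT	32.3738
AAGA	17.1867
AAGC	3.21823
AAGG	2.88944
AAGT	16.9196
AATA	166.317
AATC	16.0855
AATG	25.7203
AATT	136.874
ACAA	23.3754
ACAC	4.0421
ACAG	3.18241
ACAT	16.4116
ACCA	3.61489
ACCC	0.426468
ACCG	0.553318
ACCT	3.50941
ACGA	3.35918
ACGC	0.462548
ACGG	0.608629
ACGT	2.21948
ACTA	14.0152
ACTC	3.65702
ACTG	2.30165
ACTT	16.9196
AGAA	31.313
AGAC	3.37866
AGAG	2.57259
AGAT	15.3483
AGCA	3.10494
AGCC	0.841605
AGCG	0.7393
AGCT	3.26437
AGGA	2.49033
AGGC	0.654805
AGGG	0.551236
AGGT	3.50941
AGTA	22.2597
AGTC	2.54756
AGTG	2.44527
AGTT	32.3738
ATAA	85.5325
ATAC	24.6719
ATAG	33.97
ATAT	169.506
ATCA	14.7141
ATCC	2.5705
ATCG	3.29637
ATCT	15.3483
ATGA	26.3552
ATGC	3.51819
ATGG	4.08004
ATGT	16.4116
ATTA	175.934
ATTC	19.6769
ATTG	29.4388
ATTT	140.174
CAAA	28.1881
CAAC	4.47207
CAAG	3.86051
CAAT	29.4388
CACA	2.68865
CACC	0.823397
CACG	0.531777
CACT	2.44527
CAGA	3.03137
CAGC	0.511077
CAGG	0.705811
CAGT	2.30165
CATA	33.8419
CATC	6.78485
CATG	2.94624
CATT	25.7203
CCAA	3.51719
CCAC	0.509004
CCAG	0.612009
CCAT	4.08004
CCCA	0.667679
CCCC	0.146051
CCCG	0.0790359
CCCT	0.551236
CCGA	0.472654
CCGC	0.0986689
CCGG	0.0806108
CCGT	0.608629
CCTA	2.65071
CCTC	0.50859
CCTG	0.705811
CCTT	2.88944
CGAA	3.07365
CGAC	0.604482
CGAG	0.667658
CGAT	3.29637
CGCA	0.513109
CGCC	0.0857386
CGCG	0.122049
CGCT	0.7393
CGGA	0.373719
CGGC	0.10961
CGGG	0.0790359
CGGT	0.553318
CGTA	2.44557
CGTC	0.358217
CGTG	0.531777
CGTT	3.49454
CTAA	24.54
CTAC	4.01127
CTAG	3.54166
CTAT	33.97
CTCA	2.81717
CTCC	0.759982
CTCG	0.667658
CTCT	2.57259
CTGA	2.51809
CTGC	0.804924
CTGG	0.612009
CTGT	3.18241
CTTA	38.7543
CTTC	5.4188
CTTG	3.86051
CTTT	23.3451
GAAA	30.8547
GAAC	5.66418
GAAG	5.4188
GAAT	19.6769
GACA	3.20148
GACC	0.54734
GACG	0.358217
GACT	2.54756
GAGA	4.72121
GAGC	0.740529
GAGG	0.50859
GAGT	3.65702
GATA	22.5852
GATC	4.24189
GATG	6.78485
GATT	16.0855
GCAA	3.32712
GCAC	0.623767
GCAG	0.804924
GCAT	3.51819
GCCA	0.53871
GCCC	0.0909962
GCCG	0.10961
GCCT	0.654805
GCGA	0.577366
GCGC	0.0716644
GCGG	0.0986689
GCGT	0.462548
GCTA	2.42453
GCTC	0.740529
GCTG	0.511077
GCTT	3.21823
GGAA	5.07586
GGAC	0.446894
GGAG	0.759982
GGAT	2.5705
GGCA	0.781988
GGCC	0.0913856
GGCG	0.0857386
GGCT	0.841605
GGGA	0.56047
GGGC	0.0909962
GGGG	0.146051
GGGT	0.426468
GGTA	3.34033
GGTC	0.54734
GGTG	0.823397
GGTT	2.67736
GTAA	24.6536
GTAC	3.88999
GTAG	4.01127
GTAT	24.6719
GTCA	3.08962
GTCC	0.446894
GTCG	0.604482
GTCT	3.37866
GTGA	3.59761
GTGC	0.623767
GTGG	0.509004
GTGT	4.0421
GTTA	16.8974
GTTC	5.66418
GTTG	4.47207
GTTT	30.3611
TAAA	150.895
TAAC	16.8974
TAAG	38.7543
TAAT	175.934
TACA	14.7907
TACC	3.34033
TACG	2.44557
TACT	22.2597
TAGA	15.9799
TAGC	2.42453
TAGG	2.65071
TAGT	14.0152
TATA	114.283
TATC	22.5852
TATG	33.8419
TATT	166.317
TCAA	23.0659
TCAC	3.59761
TCAG	2.51809
TCAT	26.3552
TCCA	3.86112
TCCC	0.56047
TCCG	0.373719
TCCT	2.49033
TCGA	1.77271
TCGC	0.577366
TCGG	0.472654
TCGT	3.35918
TCTA	15.9799
TCTC	4.72121
TCTG	3.03137
TCTT	17.1867
TGAA	35.1951
TGAC	3.08962
TGAG	2.81717
TGAT	14.7141
TGCA	3.39589
TGCC	0.781988
TGCG	0.513109
TGCT	3.10494
TGGA	3.86112
TGGC	0.53871
TGGG	0.667679
TGGT	3.61489
TGTA	14.7907
TGTC	3.20148
TGTG	2.68865
TGTT	12.9984
TTAA	111.544
TTAC	24.6536
TTAG	24.54
TTAT	85.5325
TTCA	35.1951
TTCC	5.07586
TTCG	3.07365
TTCT	31.313
TTGA	23.0659
TTGC	3.32712
TTGG	3.51719
TTGT	23.3754
TTTA	150.895
TTTC	30.8547
TTTG	28.1881
TTTT	104.478
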