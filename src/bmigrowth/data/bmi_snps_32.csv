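chrom,gene,rsid,effect_allele,other_allele,gwas_beta,eaf_alspac,eaf_raine
1,NEGR1,rs2568958,A,G,0.13,0.5956,0.6218
1,TNNI3K,rs1514175,A,G,0.07,0.4249,0.4360
1,PTBP2,rs1555543,C,A,0.06,0.5905,0.5942
1,SEC16B,rs543874,G,A,0.22,0.2075,0.2021
2,TMEM18,rs2867125,C,T,0.31,0.8325,0.8303
2,"RBJ, ADCY3, POMC",rs713586,C,T,0.14,0.4888,0.4841
2,FANCL,rs887912,T,C,0.1,0.2904,0.2929
2,LRP1B,rs2890652,C,T,0.09,0.1669,0.1627
3,CADM2,rs13078807,G,A,0.1,0.2025,0.2089
3,"ETV5, DGKG, SFRS10",rs7647305,C,T,0.14,0.7924,0.7934
4,SLC39A8,rs13107325,T,C,0.19,0.0764,0.0723
4,GNPDA2,rs10938397,G,A,0.18,0.4342,0.4359
5,"FLJ35779, HMGCR",rs2112347,T,G,0.1,0.6401,0.6347
5,ZNF608,rs4836133,A,C,0.07,0.4949,0.4920
6,TFAP2B,rs987237,G,A,0.13,0.1770,0.1897
9,LRRN6C,rs10968576,G,A,0.11,0.3167,0.3062
9,LMX1B,rs867559,G,A,0.24,0.1983,0.1968
11,"RPL27A, TUB",rs4929949,C,T,0.06,0.5390,0.5210
11,BDNF,rs6265,C,T,0.19,0.8122,0.8119
11,"MTCH2, NDUFS3, CUGBP1",rs3817334,T,C,0.06,0.4000,0.4213
12,FAIM2,rs7138803,A,G,0.12,0.3592,0.3675
13,"MTIF3, GTF3A",rs4771122,G,A,0.09,0.2304,0.2154
14,PRKD1,rs11847697,T,C,0.17,0.0467,0.0414
14,NRXN3,rs10150332,C,T,0.13,0.2112,0.2183
15,"MAP2K5, LBXCOR1",rs2241423,G,A,0.13,0.7850,0.7699
16,"GPRC5B, IQCK",rs12444979,C,T,0.17,0.8620,0.8541
16,"SH2B1, ATXN2L, TUFM, ATP2A1",rs7359397,T,C,0.15,0.4166,0.3791
16,FTO,rs9939609,A,T,0.39,0.3933,0.3835
18,MC4R,rs12970134,A,G,0.23,0.2680,0.2547
19,KCTD15,rs29941,G,A,0.06,0.6848,0.6606
19,"TMEM160, ZC3H4",rs3810291,A,G,0.09,0.6941,0.6438
19,"QPCTL, GIPR",rs2287019,C,T,0.15,0.8123,0.8127
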