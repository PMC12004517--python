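lam	lam1	lam2	alpha	u0
0.0	0.0	0.0	0.1	110.0
0.047619047619047616	0.0	0.09523809523809523	0.1	110.0
0.09523809523809523	0.0	0.19047619047619047	0.1	110.0
0.14285714285714285	0.0	0.2857142857142857	0.1	110.0
0.19047619047619047	0.0	0.38095238095238093	0.1	110.0
0.23809523809523808	0.0	0.47619047619047616	0.1	110.0
0.2857142857142857	0.0	0.5714285714285714	0.1	110.0
0.3333333333333333	0.0	0.6666666666666666	0.1	110.0
0.38095238095238093	0.0	0.7619047619047619	0.1	110.0
0.42857142857142855	0.0	0.8571428571428571	0.1	110.0
0.47619047619047616	0.0	0.9523809523809523	0.1	110.0
0.5238095238095238	0.04761904761904767	1.0	0.1	110.0
0.5714285714285714	0.1428571428571428	1.0	0.1	110.0
0.6190476190476191	0.23809523809523814	1.0	0.1	110.0
0.6666666666666666	0.33333333333333326	1.0	0.1	110.0
0.7142857142857143	0.4285714285714286	1.0	0.1	110.0
0.7619047619047619	0.5238095238095237	1.0	0.1	110.0
0.8095238095238095	0.6190476190476191	1.0	0.1	110.0
0.8571428571428571	0.7142857142857142	1.0	0.1	110.0
0.9047619047619048	0.8095238095238095	1.0	0.1	110.0
0.9523809523809523	0.9047619047619047	1.0	0.1	110.0
1.0	1.0	1.0	0.1	110.0
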