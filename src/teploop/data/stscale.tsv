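# ST-scale amino acid descriptors (8 components per residue).
# Source: Yang L, Shu M, Ma K, Mei H, Jiang Y, Li Z. "ST-scale as a novel amino
# acid descriptor and its application in QSAM of peptides and analogues",
# Amino Acids 38:805-816 (2010). Principal components of 827 structural and
# topological variables. Values transcribed from the published table.
aa	ST1	ST2	ST3	ST4	ST5	ST6	ST7	ST8
A	-1.552	-0.791	-0.627	0.237	-0.461	-2.229	0.283	1.221
C	-1.276	-0.401	0.134	0.859	-0.196	-0.720	0.639	-0.857
D	-0.907	-0.054	-0.781	-0.248	1.120	0.101	-0.245	-0.075
E	-0.629	0.390	-0.380	-0.366	0.635	0.514	0.175	0.367
F	0.234	-0.606	0.405	0.192	-0.577	0.680	-0.944	-0.211
G	-1.844	-0.018	-0.184	0.573	-0.728	-3.317	0.166	2.522
H	-0.225	0.361	0.079	-1.037	0.568	0.273	1.208	-0.001
I	-0.785	-1.010	-0.349	-0.097	-0.402	1.091	-0.139	-0.764
K	-0.504	0.245	0.297	-0.065	-0.387	1.011	0.525	0.553
L	-0.826	-0.379	0.038	-0.059	-0.625	1.025	-0.229	-0.129
M	-0.693	0.498	0.658	0.457	-0.231	1.064	0.248	-0.778
N	-0.888	-0.057	-0.651	-0.214	0.917	0.164	-0.140	-0.166
P	-1.049	-0.407	-0.067	-0.066	-0.813	-0.890	0.021	-0.894
Q	-0.662	0.228	-0.193	-0.105	0.418	0.474	0.172	0.408
R	-0.059	0.731	-0.013	-0.096	-0.253	0.300	1.256	0.854
S	-1.343	-0.311	-0.917	-0.049	0.549	-1.533	0.166	0.280
T	-1.061	-0.928	-0.911	-0.063	0.538	-0.775	-0.147	-0.717
V	-1.133	-0.893	-0.325	0.303	-0.561	-0.175	-0.020	-0.311
W	0.795	0.668	1.731	0.499	-0.869	0.043	-0.405	-0.213
Y	0.308	0.569	1.100	0.350	-0.064	-0.061	-0.637	-0.491
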