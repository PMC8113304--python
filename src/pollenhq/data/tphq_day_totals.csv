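day,n_detects,tphq,total_conc_ng_g
2,7,90,571
5,6,51,88
6,5,174,53
7,10,142,387
8,13,183,1484
10,10,98,8837
11,10,80,6517
14,11,68,1851
15,8,50,827
16,13,67,335
20,7,53,77
24,11,68,330
25,10,71,249
28,11,53,787
41,7,166,268
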