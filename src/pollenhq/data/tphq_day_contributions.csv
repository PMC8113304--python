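day,analyte,phq,conc_ng_g
2,Thiacloprid,11.6,201
2,Methiocarb,70.1,5.61
2,Myclobutanil,6.77,227
2,Boscalid,0.05,7.5
2,Flonicamid,0.25,25.2
2,Difenoconazole,0.03,4.6
2,Fenpyroximate,0.84,99
5,Thiacloprid,1.1,18.9
5,Methiocarb,49.7,3.89
5,Myclobutanil,0.6,20.4
5,Boscalid,0.15,25.4
5,Flonicamid,0.13,13.1
5,Fenpyroximate,0.04,4.85
6,Thiacloprid,0.2,3.99
6,Methiocarb,174,13.9
6,Myclobutanil,0.34,11.5
6,Boscalid,0.02,3.22
6,Flonicamid,0.19,19.2
7,Thiacloprid,0.4,7.5
7,Methiocarb,138,11.0
7,Myclobutanil,0.35,12.0
7,Trifloxystrobin,0.06,7.0
7,Boscalid,0.08,14.0
7,Flonicamid,0.35,35.0
7,Fluopyram,1.23,126
7,Tebuconazole,1.1,92
7,Tebufenozide,0.75,75
7,Pyrimethanil,0.07,7.44
8,Thiacloprid,14.9,258
8,Methiocarb,138,11.0
8,Myclobutanil,9.93,334
8,Trifloxystrobin,0.59,65.0
8,Boscalid,0.08,13.0
8,Flonicamid,0.13,13.4
8,Fluopyram,0.46,47.0
8,Tebuconazole,0.59,49.0
8,Tebufenozide,4.12,412
8,Pyrimethanil,0.52,52.0
8,Difenoconazole,0.23,40.0
8,Fenpyroximate,0.57,68.0
8,Diflubenzuron,13.3,121
10,Thiacloprid,1.2,21.0
10,Myclobutanil,0.68,23.0
10,Trifloxystrobin,0.44,48.0
10,Boscalid,0.04,6.0
10,Flonicamid,0.12,12.0
10,Fluopyram,39.6,4046
10,Tebuconazole,54.5,4527
10,Tebufenozide,0.58,58.0
10,Pyrimethanil,0.46,46.0
10,Difenoconazole,0.27,48.0
11,Thiacloprid,0.7,12.0
11,Methiocarb,7.4,0.59
11,Myclobutanil,1.2,41.7
11,Trifloxystrobin,0.24,26.0
11,Flonicamid,0.15,15.0
11,Fluopyram,31.3,3169
11,Tebuconazole,38.2,3171
11,Tebufenozide,0.41,41.0
11,Fenpyroximate,0.24,28.0
11,Thiophanate-methyl,0.10,11.9
14,Thiacloprid,2.3,47.1
14,Methiocarb,46.1,3.69
14,Myclobutanil,0.37,12.5
14,Trifloxystrobin,1.5,159
14,Flonicamid,0.18,17.9
14,Fluopyram,9.7,994
14,Tebuconazole,5.9,485
14,Tebufenozide,0.55,55.4
14,Pyrimethanil,0.09,8.98
14,Thiophanate-methyl,0.51,58.7
14,Pyraclostrobin,0.07,7.73
15,Thiacloprid,0.7,11.4
15,Methiocarb,40.9,3.27
15,Myclobutanil,0.15,5.0
15,Trifloxystrobin,0.35,38.4
15,Flonicamid,0.09,8.55
15,Fluopyram,5.2,525
15,Tebuconazole,2.6,217
15,Tebufenozide,0.16,16.4
16,Thiacloprid,2.4,41.3
16,Methiocarb,61.5,4.92
16,Myclobutanil,0.25,8.58
16,Trifloxystrobin,0.8,88.0
16,Boscalid,0.51,84.2
16,Flonicamid,0.06,5.77
16,Fluopyram,0.24,24.7
16,Tebuconazole,0.10,8.3
16,Tebufenozide,0.25,25.3
16,Pyrimethanil,0.07,6.99
16,Dimoxystrobin,0.08,6.12
16,Kresoxim-methyl,0.18,10.5
16,Pyraclostrobin,0.01,19.4
20,Thiacloprid,0.5,9.13
20,Methiocarb,51,4.08
20,Trifloxystrobin,0.16,17.6
20,Boscalid,0.12,19.5
20,Flonicamid,0.06,5.53
20,Acetamiprid,0.73,10.6
20,Thiophanate-methyl,0.09,9.8
24,Thiacloprid,2.2,37.5
24,Methiocarb,62.6,5.0
24,Myclobutanil,0.26,8.79
24,Trifloxystrobin,1.2,136
24,Boscalid,0.04,6.44
24,Flonicamid,0.47,48.3
24,Fluopyram,0.15,14.9
24,Difenoconazole,0.03,6.08
24,Fenpyroximate,0.4,47.4
24,Cyprodinil,0.09,10.1
24,Azoxystrobin,0.3,7.56
25,Thiacloprid,1.8,30.7
25,Methiocarb,66.6,5.33
25,Trifloxystrobin,1.1,119
25,Boscalid,0.03,5.15
25,Fluopyram,0.43,44.5
25,Tebuconazole,0.3,24.66
25,Tebufenozide,0.07,5.73
25,Pyrimethanil,0.07,6.5
25,Difenoconazole,0.02,4.19
25,Acetamiprid,0.22,2.6
28,Thiacloprid,6.8,118
28,Methiocarb,40.1,3.2
28,Trifloxystrobin,2.2,238
28,Boscalid,0.04,6.71
28,Fluopyram,1.9,194
28,Tebufenozide,0.08,8.36
28,Difenoconazole,0.02,3.06
28,Cyprodinil,1.7,191
28,Azoxystrobin,0.3,6.49
28,Fenpyroximate,0.12,14.1
28,Dimoxystrobin,0.05,3.61
41,Thiacloprid,0.6,10.3
41,Methiocarb,162,13
41,Myclobutanil,0.43,14.5
41,Trifloxystrobin,0.12,13.5
41,Tebuconazole,1.9,156
41,Acetamiprid,0.68,9.83
41,Fenpyroximate,0.08,10.0
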