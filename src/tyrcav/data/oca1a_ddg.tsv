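mutation	ddg	unfolding_published	ddv_published	ddsa_published
H180N	-0.95	0.17	563	705
H180R	2.16	0.97	1178	1020
H202R	2.81	0.99	66	49
H202Q	1.36	0.91	-294	54
H211R	9.24	1.00	-435	-376
H363T	-1.46	0.08	1255	1419
H363R	-0.80	0.21	1505	1610
H363Y	1.58	0.93	-632	-314
H367Y	0.93	0.82	-285	-36
H367R	-0.91	0.18	813	927
H390D	-0.17	0.43	-178	146
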