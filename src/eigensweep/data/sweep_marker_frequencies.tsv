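hotspot_id	marker_id	position_cM	allele_group1	freq_group1	allele_group2	freq_group2
eigenQTL2A.7	1089372	123.66	0	0.81	1	0.82
eigenQTL2A.7	1096089	123.66	0	0.81	1	0.90
eigenQTL2A.7	1288584	123.66	1	0.80	0	0.90
eigenQTL2B.3	3935165	36.35	0	0.89	1	0.82
eigenQTL2B.3	3946438	36.35	0	0.84	1	0.87
eigenQTL2B.3	3955840	36.35	0	0.84	1	0.87
eigenQTL2B.3	4404794	36.35	1	1.00	0	0.85
eigenQTL2B.3	4404891	36.35	1	1.00	0	0.85
eigenQTL2B.3	4409154	36.35	1	1.00	0	0.85
eigenQTL2B.3	3022498	37.15	0	0.84	1	0.80
eigenQTL2B.3	1125733	38.57	0	0.89	1	0.80
eigenQTL2B.3	1353553	40.74	C	0.84	T	0.87
eigenQTL2B.3	3021610	40.74	C	0.89	T	0.87
eigenQTL2B.3	4004228	40.74	1	0.95	0	0.85
eigenQTL2B.3	4004312	40.99	1	0.95	0	0.82
eigenQTL2B.3	986135	40.99	A	0.89	C	0.85
eigenQTL2B.3	1124640	41.86	A	0.84	G	0.85
eigenQTL3A.6	2257732	103.85	0	0.98	1	0.98
eigenQTL3A.6	1007286	103.92	0	0.98	1	0.95
eigenQTL3A.6	1061286	103.92	0	0.99	1	0.88
eigenQTL3A.6	1099726	103.92	0	0.98	1	0.97
eigenQTL3A.6	2257138	103.92	0	0.98	1	0.99
eigenQTL3A.6	3033940	103.92	0	0.96	1	0.99
eigenQTL3A.6	3940178	103.92	0	0.97	1	0.99
eigenQTL3A.6	3945420	103.92	0	0.98	1	0.96
eigenQTL3A.6	3952975	103.92	0	0.98	1	0.98
eigenQTL3A.6	3957848	103.92	0	0.97	1	0.99
eigenQTL3A.6	4005072	103.92	0	0.97	1	0.99
eigenQTL3A.7	1062254	110.13	T	0.98	G	0.98
eigenQTL3A.7	1120615	110.13	1	0.95	0	0.96
eigenQTL3A.7	1127998	110.13	T	0.93	C	0.96
eigenQTL3A.7	1755023	110.13	1	0.99	0	0.96
eigenQTL3A.7	2275425	110.13	A	0.98	G	0.97
eigenQTL3A.7	4003435	110.13	1	0.99	0	0.96
eigenQTL3A.7	4004625	110.13	1	0.98	0	0.97
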