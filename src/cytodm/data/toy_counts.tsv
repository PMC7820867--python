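sample_id	OTU_1	OTU_2	OTU_3	OTU_4	OTU_5	OTU_6
P1_T	120	40	13	1	0	6
P1_H	110	52	9	0	1	8
P2_T	95	60	20	2	1	2
P2_H	90	66	15	1	0	8
P3_T	130	30	25	0	2	13
P3_H	125	41	18	1	1	14
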