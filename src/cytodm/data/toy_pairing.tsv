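patient_id	tumor_sample_id	healthy_sample_id
P1	P1_T	P1_H
P2	P2_T	P2_H
P3	P3_T	P3_H
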