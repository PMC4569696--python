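mirna	fold_change_adult_vs_p10	adjusted_p	mean_p10_log2	mean_adult_log2
miR-17-5p	-4.2	2.28e-04	8.01	5.94
miR-18a	-3.7	1.97e-04	6.44	4.56
miR-19b	-4.5	5.98e-04	11.30	9.13
miR-20a	-3.6	3.65e-04	9.50	7.64
miR-92a	-4.3	4.47e-03	10.43	8.31
miR-25	-2.3	8.46e-03	10.00	8.81
miR-93	-2.9	2.67e-04	8.48	6.97
miR-106b	-2.2	5.11e-04	10.96	9.79
miR-192	-6.8	1.37e-02	10.85	8.09
miR-194	-9.5	8.70e-03	10.16	6.91
miR-215	-139.2	5.82e-04	9.62	2.50
miR-130b	-5.3	8.92e-04	7.96	5.57
miR-181b	-5.1	3.86e-03	7.68	5.35
miR-203	-6.9	2.58e-03	7.60	4.81
miR-29b	8.6	2.53e-04	10.60	13.71
miR-129	5.7	4.60e-03	5.86	8.36
miR-204	3.8	3.65e-04	7.51	9.44
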