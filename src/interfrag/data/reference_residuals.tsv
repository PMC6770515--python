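system_id	vacuum_dry	vacuum_shell1	vacuum_shell2	vacuum_shell3	cosmo_dry	cosmo_shell1	cosmo_shell2	cosmo_shell3	cosmo_shell3_nointercept
3ptb_ben	3.70	3.18	2.90	1.93	3.73	2.33	2.45	1.18	0.85
3ptb_pme	3.60	3.09	3.05	2.03	0.53	1.12	2.48	0.95	1.22
3ptb_pam	1.74	1.29	0.88	0.03	0.01	0.02	0.44	0.92	3.03
3ptb_pmo	4.45	3.91	3.71	2.64	3.59	3.25	3.32	2.24	0.33
3ptb_pad	5.65	5.11	5.04	4.25	3.03	3.12	4.32	3.22	1.37
1k1l	0.56	0.39	0.10	0.10	2.59	1.05	0.56	0.43	1.74
1k1m	0.16	0.56	0.36	0.79	2.71	1.17	0.75	1.50	3.12
1k1i	2.67	3.19	2.95	3.51	2.80	3.62	2.88	3.34	4.60
1k1j	1.43	1.81	1.60	2.10	0.57	2.60	1.47	2.32	3.75
1jyr	0.78	0.28	0.53	0.09	1.73	0.36	0.40	0.53	0.36
1rlq	0.67	0.64	0.27	0.33	0.37	2.13	0.61	0.24	0.16
2ke1	2.54	4.67	4.66	5.28	4.38	4.21	5.73	2.46	2.89
2bba	7.25	6.38	7.21	6.23	4.34	2.13	6.58	3.77	3.31
1jgn	5.88	5.24	4.75	2.56	1.61	0.27	3.25	0.25	1.36
2roc	4.96	4.11	3.74	1.26	2.76	1.24	3.05	1.71	3.92
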