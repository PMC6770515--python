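# Published regression statistics per solvent model (two-decimal print
# precision).  t_beta is absent for the no-intercept model.
model	r2	r2_cv	F	rmse	t_alpha	t_beta
vacuum_dry	0.06	0.00	0.81	4.02	0.90	-5.56
vacuum_shell1	0.18	0.01	2.77	3.76	1.66	-5.04
vacuum_shell2	0.19	0.02	3.14	3.72	1.77	-4.68
vacuum_shell3	0.44	0.22	10.20	3.10	3.19	-3.90
cosmo_dry	0.51	0.34	13.46	2.90	3.67	-2.18
cosmo_shell1	0.65	0.54	24.28	2.45	4.93	-3.99
cosmo_shell2	0.33	0.07	6.36	3.40	2.52	-4.24
cosmo_shell3	0.73	0.65	34.55	2.17	5.88	-2.81
cosmo_shell3_nointercept	0.93	0.91	179.66	2.65	13.40	NA
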