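# Per-time-point summary statistics and per-T-allele regression estimates for
# each consumption phenotype, used to parameterize the synthetic cohort
# generator. units: total = mg/day; coffee, tea = drinks/day; cola = drinks/week.
# Columns: phenotype, time point, analysed N, phenotype mean and SD (min/max of
# the observed range), then beta/SE/p for rs2472297, rs6968865 and the
# unweighted combined T-allele score.
phenotype	time_point	n	mean	sd	min	max	beta_rs2472297	se_rs2472297	p_rs2472297	beta_rs6968865	se_rs6968865	p_rs6968865	beta_combined	se_combined	p_combined
total	8wk	6785	206.8	142.4	0	1201	8.7	2.7	1.59e-03	4.0	2.5	1.15e-01	5.9	1.8	1.15e-03
total	18wk	7356	215.3	142.4	0	1161	12.4	2.6	2.29e-06	7.9	2.4	1.08e-03	9.7	1.8	2.94e-08
total	32wk	6898	216.0	141.5	0	1150	14.6	2.7	5.85e-08	5.6	2.5	2.36e-02	9.5	1.8	1.31e-07
total	2mo	4659	233.5	154.8	0	1350	11.8	3.6	9.54e-04	7.7	3.3	1.90e-02	9.3	2.4	9.74e-05
total	47mo	5894	302.5	149.6	0	1150	16.8	3.1	4.47e-08	11.0	2.8	1.09e-04	13.2	2.0	1.04e-10
total	85mo	5199	306.1	150.5	0	1152	16.0	3.3	1.05e-06	13.7	3.0	6.34e-06	14.2	2.2	7.38e-11
total	97mo	4958	299.3	147.1	0	1160	15.8	3.3	1.49e-06	10.9	3.0	3.04e-04	12.7	2.2	5.80e-09
total	145mo	4460	278.3	144.9	0	1185	21.4	3.4	3.33e-10	14.6	3.1	3.34e-06	17.1	2.3	3.74e-14
coffee	8wk	7102	1.18	1.66	0	10	0.069	0.031	2.62e-02	0.031	0.029	2.79e-01	0.047	0.021	2.34e-02
coffee	18wk	7520	1.25	1.68	0	10	0.082	0.031	7.47e-03	0.078	0.028	5.39e-03	0.078	0.020	1.36e-04
coffee	32wk	7076	1.24	1.66	0	10	0.110	0.031	4.35e-04	0.037	0.029	1.99e-01	0.068	0.021	1.02e-03
coffee	2mo	4774	1.47	1.92	0	10	0.105	0.044	1.67e-02	0.107	0.040	8.31e-03	0.102	0.029	4.59e-04
coffee	47mo	5953	2.26	2.14	0	10	0.134	0.044	2.22e-03	0.111	0.040	6.09e-03	0.118	0.029	5.46e-05
coffee	85mo	5279	2.30	2.16	0	10	0.081	0.047	8.42e-02	0.096	0.043	2.74e-02	0.086	0.031	6.10e-03
coffee	97mo	5046	2.22	2.11	0	10	0.096	0.047	4.06e-02	0.099	0.043	2.07e-02	0.095	0.031	2.35e-03
coffee	145mo	4532	2.05	1.97	0	10	0.113	0.046	1.34e-02	0.132	0.042	1.76e-03	0.120	0.031	9.01e-05
tea	8wk	7120	2.73	2.30	0	15	0.103	0.043	1.74e-02	0.057	0.040	1.48e-01	0.076	0.029	8.31e-03
tea	18wk	7515	2.78	2.28	0	15	0.133	0.042	1.40e-03	0.052	0.038	1.76e-01	0.087	0.028	1.80e-03
tea	32wk	7056	2.95	2.27	0	15	0.133	0.043	1.83e-03	0.081	0.039	3.99e-02	0.102	0.028	3.45e-04
tea	2mo	5340	3.05	2.42	0	15	0.128	0.052	1.42e-02	0.040	0.048	4.11e-01	0.077	0.035	2.58e-02
tea	47mo	5957	3.17	2.48	0	15	0.170	0.051	7.48e-04	0.084	0.047	7.22e-02	0.120	0.034	3.82e-04
tea	85mo	5303	3.18	2.52	0	15	0.239	0.054	1.01e-05	0.157	0.050	1.79e-03	0.187	0.036	2.08e-07
tea	97mo	5051	3.18	2.47	0	15	0.224	0.055	4.21e-05	0.083	0.050	1.00e-01	0.143	0.036	9.01e-05
tea	145mo	4632	2.98	2.38	0	15	0.317	0.055	6.80e-09	0.127	0.051	1.24e-02	0.209	0.037	1.23e-08
cola	8wk	6876	2.31	4.20	0	21	0.116	0.080	1.50e-01	-0.113	0.074	1.23e-01	-0.009	0.054	8.68e-01
cola	18wk	7412	2.12	4.13	0	21	0.078	0.076	3.07e-01	-0.019	0.070	7.89e-01	0.025	0.051	6.25e-01
cola	32wk	6976	1.31	2.50	0	21	0.014	0.047	7.73e-01	-0.027	0.043	5.28e-01	-0.008	0.032	7.91e-01
cola	2mo	5243	0.60	1.66	0	21	-0.021	0.036	5.64e-01	-0.071	0.033	3.43e-02	-0.046	0.024	5.51e-02
cola	47mo	6023	1.47	2.10	0	7	0.004	0.043	9.26e-01	-0.064	0.039	1.07e-01	-0.032	0.029	2.69e-01
cola	85mo	5315	1.36	2.03	0	7	-0.019	0.044	6.61e-01	0.010	0.041	7.96e-01	-0.003	0.029	9.15e-01
cola	97mo	5096	1.33	2.00	0	7	0.035	0.044	4.34e-01	0.032	0.041	4.27e-01	0.032	0.029	2.73e-01
cola	145mo	4685	0.97	1.72	0	7	0.029	0.039	4.61e-01	0.018	0.036	6.25e-01	0.022	0.026	3.96e-01
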