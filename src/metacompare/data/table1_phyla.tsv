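taxon	mean_guinea_pig	sd_guinea_pig	mean_human	sd_human	p_value	q_value
Synergistetes	0.14	0.038	0.033	0.018	2.29E-06	3.08E-05
Chlorobi	1.2	0.26	0.31	0.19	2.52E-06	3.08E-05
Unclassified	37	5.9	25	3.6	3.65E-06	3.08E-05
Fusobacteria	0.52	0.16	0.14	0.094	4.01E-06	3.08E-05
Deferribacteres	0.12	0.016	0.048	0.02	4.81E-06	3.08E-05
Euryarchaeota	1.8	0.39	0.62	0.36	7.22E-06	3.77E-05
Cyanobacteria	0.5	0.088	0.22	0.1	8.25E-06	3.77E-05
Thermotogae	0.21	0.024	0.098	0.042	1.03E-05	4.12E-05
Chlamydiae	0.25	0.047	0.12	0.061	2.06E-05	7.18E-05
Chloroflexi	0.06	0.012	0.027	0.012	2.24E-05	7.18E-05
Chrysiogenetes	0.046	0.011	0.021	0.015	3.42E-05	9.90E-05
Planctomycetes	0.026	0.011	0.0099	0.0051	3.71E-05	9.90E-05
Korarchaeota	0.00075	0.00029	0.00025	0.00047	5.37E-05	0.000132183
Bacteroidetes	15	3.3	27	10	8.03E-05	0.000183527
Fibrobacteres	0.13	0.028	0.058	0.083	0.000105854	0.000225823
Spirochaetes	1.2	0.095	0.66	0.35	0.000123729	0.000247458
Verrucomicrobia	2.1	2	0.38	0.66	0.000174881	0.000322945
Thermodesulfobacteria	0.0024	0.00062	0.0012	0.0012	0.000181657	0.000322945
Proteobacteria	9.4	1.6	6.4	2.7	0.000526935	0.000887469
Nitrospirae	0.032	0.0076	0.019	0.01	0.000628535	0.001005656
Acidobacteria	0.25	0.07	0.16	0.087	0.002879726	0.004388154
Deinococcus-Thermus	0.031	0.011	0.061	0.031	0.004035327	0.005869567
Aquificae	0.016	0.0037	0.024	0.0098	0.005763463	0.008018731
Firmicutes	29	6.3	37	9.3	0.015217931	0.020290574
Tenericutes	0.21	0.093	0.15	0.13	0.020738726	0.025524586
Thaumarchaeota	0.011	0.0027	0.0084	0.0065	0.020738726	0.025524586
Actinobacteria	1.3	0.34	2	1.1	0.052286556	0.061969251
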