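# Specimen metadata for the published G. marginata COI barcode survey:
# 97 ingroup specimens with collection coordinates (decimal degrees, S/W
# negative) and bioregion codes, plus the 21 congeneric outgroup specimens
# (no coordinates/bioregions were published for the outgroups).
# Correction: the source table prints longitude "E6775" for G.mar.74 and
# G.mar.75; this is stored here as the evident intended value 6.775.
specimen_id	taxon	latitude	longitude	bioregion
G.mar.01	Glomeris marginata	51.743	10.767	DE.MGSO
G.mar.02	Glomeris marginata	51.744	10.767	DE.MGSO
G.mar.03	Glomeris marginata	51.841	10.326	DE.MGSO
G.mar.04	Glomeris marginata	50.895	11.753	DE.MGSO
G.mar.05	Glomeris marginata	50.895	11.753	DE.MGSO
G.mar.06	Glomeris marginata	50.919	11.548	DE.MGSO
G.mar.07	Glomeris marginata	50.919	11.548	DE.MGSO
G.mar.08	Glomeris marginata	50.892	11.821	DE.MGSO
G.mar.09	Glomeris marginata	50.892	11.821	DE.MGSO
G.mar.10	Glomeris marginata	51.133	11.749	DE.MGSO
G.mar.11	Glomeris marginata	51.133	11.749	DE.MGSO
G.mar.12	Glomeris marginata	50.663	7.103	DE.MGSW
G.mar.13	Glomeris marginata	50.666	7.216	DE.MGSW
G.mar.14	Glomeris marginata	50.687	7.300	DE.MGSW
G.mar.15	Glomeris marginata	50.767	7.367	DE.MGSW
G.mar.16	Glomeris marginata	51.361	7.550	DE.MGSW
G.mar.17	Glomeris marginata	51.361	7.550	DE.MGSW
G.mar.18	Glomeris marginata	50.560	6.808	DE.MGSW
G.mar.19	Glomeris marginata	51.230	7.054	DE.MGSW
G.mar.20	Glomeris marginata	50.803	7.242	DE.MGSW
G.mar.21	Glomeris marginata	51.359	7.170	DE.MGSW
G.mar.22	Glomeris marginata	51.230	7.054	DE.MGSW
G.mar.23	Glomeris marginata	50.714	7.177	DE.MGSW
G.mar.24	Glomeris marginata	50.672	7.047	DE.MGSW
G.mar.25	Glomeris marginata	51.291	7.252	DE.MGSW
G.mar.26	Glomeris marginata	50.551	7.172	DE.MGSW
G.mar.27	Glomeris marginata	50.465	7.223	DE.MGSW
G.mar.28	Glomeris marginata	51.361	7.550	DE.MGSW
G.mar.29	Glomeris marginata	50.632	6.473	DE.MGSW
G.mar.30	Glomeris marginata	50.780	8.009	DE.MGSW
G.mar.31	Glomeris marginata	50.780	8.009	DE.MGSW
G.mar.32	Glomeris marginata	50.709	7.713	DE.MGSW
G.mar.33	Glomeris marginata	50.709	7.713	DE.MGSW
G.mar.34	Glomeris marginata	50.709	7.713	DE.MGSW
G.mar.35	Glomeris marginata	50.625	7.194	DE.MGSW
G.mar.36	Glomeris marginata	50.625	7.194	DE.MGSW
G.mar.37	Glomeris marginata	51.182	10.221	DE.MGSW
G.mar.38	Glomeris marginata	51.182	10.221	DE.MGSW
G.mar.39	Glomeris marginata	53.919	10.098	DE.NDTO
G.mar.40	Glomeris marginata	54.303	10.756	DE.NDTO
G.mar.41	Glomeris marginata	53.124	13.884	DE.NDTO
G.mar.42	Glomeris marginata	53.653	11.437	DE.NDTO
G.mar.43	Glomeris marginata	53.653	11.437	DE.NDTO
G.mar.44	Glomeris marginata	53.279	12.077	DE.NDTO
G.mar.45	Glomeris marginata	52.960	9.893	DE.NDTW
G.mar.46	Glomeris marginata	51.442	7.267	DE.NDTW
G.mar.47	Glomeris marginata	49.983	9.768	DE.SSL
G.mar.48	Glomeris marginata	49.864	9.857	DE.SSL
G.mar.49	Glomeris marginata	42.430	-2.562	ES.CC
G.mar.50	Glomeris marginata	43.234	-1.638	ES.CC
G.mar.51	Glomeris marginata	43.234	-1.638	ES.CC
G.mar.52	Glomeris marginata	41.315	1.104	ES.PYRS
G.mar.53	Glomeris marginata	45.273	5.766	FR.ALP
G.mar.54	Glomeris marginata	45.071	6.008	FR.ALP
G.mar.55	Glomeris marginata	48.201	0.171	FR.ATLN
G.mar.56	Glomeris marginata	48.230	-0.242	FR.ATLN
G.mar.57	Glomeris marginata	47.261	0.326	FR.ATLN
G.mar.58	Glomeris marginata	47.812	7.065	FR.CONN
G.mar.59	Glomeris marginata	49.461	6.364	FR.CONN
G.mar.60	Glomeris marginata	47.859	6.404	FR.CONN
G.mar.61	Glomeris marginata	47.839	6.667	FR.CONN
G.mar.62	Glomeris marginata	47.839	6.667	FR.CONN
G.mar.63	Glomeris marginata	47.817	6.874	FR.CONN
G.mar.64	Glomeris marginata	45.235	1.545	FR.CONS
G.mar.65	Glomeris marginata	44.114	5.241	FR.MED
G.mar.66	Glomeris marginata	44.114	5.241	FR.MED
G.mar.67	Glomeris marginata	44.114	5.241	FR.MED
G.mar.68	Glomeris marginata	44.551	4.949	FR.MED
G.mar.69	Glomeris marginata	43.494	5.521	FR.MED
G.mar.70	Glomeris marginata	43.464	5.800	FR.MED
G.mar.71	Glomeris marginata	43.232	6.234	FR.MED
G.mar.72	Glomeris marginata	43.974	7.311	FR.MED
G.mar.73	Glomeris marginata	44.297	4.152	FR.MED
G.mar.74	Glomeris marginata	43.589	6.775	FR.MED
G.mar.75	Glomeris marginata	43.589	6.775	FR.MED
G.mar.76	Glomeris marginata	42.412	2.566	FR.PYRN
G.mar.77	Glomeris marginata	42.997	1.010	FR.PYRN
G.mar.78	Glomeris marginata	43.017	0.480	FR.PYRN
G.mar.79	Glomeris marginata	42.375	2.456	FR.PYRN
G.mar.80	Glomeris marginata	51.750	-0.750	GB.EM
G.mar.81	Glomeris marginata	49.500	1.100	FR.ATLN
G.mar.82	Glomeris marginata	49.500	1.100	FR.ATLN
G.mar.83	Glomeris marginata	49.500	1.100	FR.ATLN
G.mar.84	Glomeris marginata	49.500	1.100	FR.ATLN
G.mar.85	Glomeris marginata	49.434	0.714	FR.ATLN
G.mar.86	Glomeris marginata	49.434	0.714	FR.ATLN
G.mar.87	Glomeris marginata	49.434	0.714	FR.ATLN
G.mar.88	Glomeris marginata	49.434	0.714	FR.ATLN
G.mar.89	Glomeris marginata	49.434	0.714	FR.ATLN
G.mar.90	Glomeris marginata	49.434	0.714	FR.ATLN
G.mar.91	Glomeris marginata	49.480	0.954	FR.ATLN
G.mar.92	Glomeris marginata	50.692	7.100	DE.MGSW
G.mar.93	Glomeris marginata	50.619	7.254	DE.MGSW
G.mar.94	Glomeris marginata	50.560	6.808	DE.MGSW
G.mar.95	Glomeris marginata	50.619	7.254	DE.MGSW
G.mar.96	Glomeris marginata	49.392	8.158	DE.SSL
G.mar.97	Glomeris marginata	42.830	-2.100	ES.CC
G.int.1	Glomeris intermedia
G.int.2	Glomeris intermedia
G.und.1	Glomeris klugii
G.und.2	Glomeris klugii
G.con.1	Glomeris connexa
G.con.2	Glomeris connexa
G.hex.1	Glomeris hexasticha
G.hex.2	Glomeris hexasticha
G.mae.1	Glomeris maerens-group
G.mae.2	Glomeris maerens-group
G.mae.3	Glomeris maerens-group
G.mae.4	Glomeris maerens-group
G.mae.5	Glomeris maerens-group
G.mae.6	Glomeris maerens-group
G.mae.7	Glomeris maerens-group
G.mae.8	Glomeris maerens-group
G.mae.9	Glomeris maerens-group
G.ann.1	Glomeris annulata
G.ann.2	Glomeris annulata
G.apu.1	Glomeris apuana
G.apu.2	Glomeris apuana
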