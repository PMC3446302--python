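deficiency	first_missing_base	last_missing_base	sex	rpm_df	rpm_wt	fold_printed
Df(2L)ED2809	67365	72671	female	29.5	54.3	1.84
Df(2L)ED2809	67365	72671	male	27.9	60.3	2.16
Df(2L)ED62	480873	826788	female	1371.5	2912.8	2.12
Df(2L)ED62	480873	826788	male	1366.1	3313.8	2.43
Df(2L)ED80	568095	850645	female	1168.28	2373.4	2.03
Df(2L)ED80	568095	850645	male	1253.1	2691.5	2.14
Df(2L)ED87	568095	852827	female	1103.5	2390.5	2.17
Df(2L)ED87	568095	852827	male	1177.3	2711.5	2.30
Df(2L)EDHsp60c	5564618	5809650	female	1060.5	2151.0	2.03
Df(2L)EDHsp60c	5564618	5809650	male	1170.1	2362.2	2.02
Df(2L)ED280	5801930	5907456	female	447.8	922.5	2.06
Df(2L)ED280	5801930	5907456	male	509.2	970.4	1.92
Df(2L)ED292	5801930	5981009	female	744.8	1510.1	2.03
Df(2L)ED292	5801930	5981009	male	804.1	1648.5	2.05
Df(2L)ED385	5980272	6465772	female	1801.7	3841.6	2.13
Df(2L)ED385	5980272	6465772	male	2130.8	4350.7	2.04
Df(2L)ED7007	6709099	6963808	female	1989.6	2107.4	1.06
Df(2L)ED7007	6709099	6963808	male	1401.4	2308.7	1.65
Df(2L)ED489	7204186	7576637	female	1692.6	3338.0	1.97
Df(2L)ED489	7204186	7576637	male	1803.2	3485.6	1.93
Df(2L)ED499	7423765	7800182	female	1727.3	3337.2	1.93
Df(2L)ED499	7423765	7800182	male	1844.5	3514.0	1.91
Df(2L)ED475	7423915	7576637	female	700.2	1428.4	2.04
Df(2L)ED475	7423915	7576637	male	786.9	1474.1	1.87
Df(2L)ED478	7437442	7576637	female	581.2	1309.2	2.26
Df(2L)ED478	7437442	7576637	male	628.7	1348.3	2.14
Df(2L)ED623	8403564	8700124	female	1335.1	2531.3	1.90
Df(2L)ED623	8403564	8700124	male	1504.1	2718.2	1.81
Df(2L)ED695	9699225	9918192	female	929.1	1858.3	2.00
Df(2L)ED695	9699225	9918192	male	1009.2	2041.9	2.02
Df(2L)ED775	12010010	12975028	female	4424.3	7821.9	1.77
Df(2L)ED775	12010010	12975028	male	4758.8	8352.9	1.76
Df(2L)ED776	12434538	12975028	female	2086.6	4337.0	2.08
Df(2L)ED776	12434538	12975028	male	2347.3	4638.7	1.98
Df(2L)ED777	12484452	12975028	female	1997.0	3910.5	1.96
Df(2L)ED777	12484452	12975028	male	2387.6	4182.3	1.75
Df(2L)ED793	13934848	14689337	female	3324.0	6563.4	1.97
Df(2L)ED793	13934848	14689337	male	3619.5	7125.3	1.97
Df(2L)ED800	14490575	15332688	female	3750.7	6968.0	1.86
Df(2L)ED800	14490575	15332688	male	4032.9	7456.4	1.85
Df(2L)ED1231	19158440	19464056	female	1266.4	2533.5	2.00
Df(2L)ED1231	19158440	19464056	male	1362.8	2789.8	2.05
Df(2L)ED1305	20085397	20382385	female	932.4	1831.8	1.96
Df(2L)ED1305	20085397	20382385	male	1003.9	2005.4	2.00
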