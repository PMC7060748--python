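individual_id	role	duration_s	phase	nursing_speed	nonnursing_mean_speed	nursing_odba	nonnursing_mean_odba	nursing_fsr	nonnursing_mean_fsr
mn180831-30	calf	13	ascending	1.6	1.9	0.1794	0.1289	0.2239	0.1816
mn170612-30	calf	15	descending	1.5	1.9	0.2722	0.2761	0.3311	0.2680
mn170613-40	calf	35	descending	1.5	1.3	0.3772	0.2209	0.3714	0.2370
mn170613-40	calf	20	descending	1.6	1.3	0.5710	0.2209	0.6863	0.2370
mn180620-40	calf	27	descending	1.3	1.5	0.1936	0.2048	0.2622	0.1927
mn170612-30	calf	31	horizontal	1.4	1.9	0.2258	0.1434	0.2932	0.1395
mn170612-30	calf	18	horizontal	1.4	1.9	0.1938	0.1434	0.2825	0.1395
mn170613-40	calf	27	horizontal	1.2	1.2	0.2448	0.1497	0.3285	0.1395
mn180620-40	calf	22	horizontal	1.3	1.4	0.1360	0.1217	0.2326	0.1174
mn180620-40	calf	28	horizontal	1.2	1.4	0.1499	0.1217	0.1079	0.1174
mn180620-40	calf	18	horizontal	1.3	1.4	0.2271	0.1217	0.2247	0.1174
mn180831-20	mother	13	ascending	1.5	2.0	0.0346	0.1554	0.0746	0.1956
mn170613-20	mother	35	descending	1.4	1.6	0.0258	0.0546	0.0000	0.0332
mn170613-20	mother	27	horizontal	1.2	1.6	0.0311	0.2290	0.0000	0.1255
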