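# Synthetic-timeline event log for the reference deployments.
# Durations, counts and phases follow the published per-event table; start
# times are synthetic placements consistent with the published narrative.
deployment_id	event_type	start_s	end_s	note
mn170612-30	nursing	3000	3015	phase=descending
mn170612-30	nursing	7000	7031	phase=horizontal
mn170612-30	nursing	11000	11018	phase=horizontal
mn170612-30	lunge	3100	3105
mn170612-30	dragging	7200	7210
mn170612-30	bottom_feeding	11100	11110
mn170612-30	probable_nursing	15000	15017
mn170612-30	poor_video	24000	24031
mn170613-40	nursing	1000	1035	phase=descending
mn170613-40	nursing	5000	5020	phase=descending
mn170613-40	nursing	9000	9027	phase=horizontal
mn170613-40	lunge	1200	1206
mn170613-40	lunge	5150	5156
mn170613-40	bottom_feeding	9040	9045	shortest gap 13 s
mn170613-40	probable_nursing	12000	12015
mn170613-40	proximity	900	1500
mn170613-40	proximity	4900	5500
mn170613-40	proximity	8900	9500
mn170613-40	proximity	12100	12523
mn180620-40	nursing	2000	2027	phase=descending
mn180620-40	nursing	6000	6022	phase=horizontal
mn180620-40	nursing	10000	10028	phase=horizontal
mn180620-40	nursing	14000	14018	phase=horizontal
mn180620-40	bottom_feeding	2400	2410
mn180620-40	lunge	6500	6505
mn180620-40	dragging	10600	10610
mn180620-40	lunge	14700	14710
mn180620-40	probable_nursing	18000	18020
mn180620-40	probable_nursing	20000	20015
mn180831-30	nursing	4000	4013	phase=ascending
mn180831-30	lunge	4600	4605
mn180831-30	poor_video	10000	10888
mn170613-20	nursing	1000	1035	phase=descending
mn170613-20	nursing	9000	9027	phase=horizontal
mn170613-20	bottom_feeding	9040	9045
mn180831-20	nursing	4000	4013	phase=ascending
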