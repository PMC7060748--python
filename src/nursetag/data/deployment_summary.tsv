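individual_id	tag_on_local	video_h	good_video_h	n_events	mean_duration_s	total_nursing_s	percent_nursing
mn170612-30	09:07 EDT	6.7	6.7	3	21	64	0.26
mn170613-40	13:17 EDT	4.2	4.2	3	28	83	0.54
mn180620-40	11:10 EDT	7.2	7.2	4	24	94	0.36
mn180831-30	07:45 PDT	3.1	2.8	1	13	13	0.13
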