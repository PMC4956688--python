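channel_id	x	y	kind	group_id
E1	0	0	eeg	loc1
E2	1	0	eeg	loc2
E3	2	0	eeg	loc3
E4	3	0	eeg	loc4
E5	0	1	eeg	loc5
E6	1	1	eeg	loc6
E7	2	1	eeg	loc7
E8	3	1	eeg	loc8
E9	0	2	eeg	loc9
E10	1	2	eeg	loc10
E11	2	2	eeg	loc11
E12	3	2	eeg	loc12
E13	0	3	eeg	loc13
E14	1	3	eeg	loc14
E15	2	3	eeg	loc15
E16	3	3	eeg	loc16
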