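channel_id	x	y	kind	group_id
x1	0	0	planar	loc1
y1	0	0	planar	loc1
x2	1	0	planar	loc2
y2	1	0	planar	loc2
x3	2	0	planar	loc3
y3	2	0	planar	loc3
x4	0	1	planar	loc4
y4	0	1	planar	loc4
x5	1	1	planar	loc5
y5	1	1	planar	loc5
x6	2	1	planar	loc6
y6	2	1	planar	loc6
x7	0	2	planar	loc7
y7	0	2	planar	loc7
x8	1	2	planar	loc8
y8	1	2	planar	loc8
x9	2	2	planar	loc9
y9	2	2	planar	loc9
c1	0	0	combined	loc1
c2	1	0	combined	loc2
c3	2	0	combined	loc3
c4	0	1	combined	loc4
c5	1	1	combined	loc5
c6	2	1	combined	loc6
c7	0	2	combined	loc7
c8	1	2	combined	loc8
c9	2	2	combined	loc9
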