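# navblock episodic sweep table
# protocol: mini
# time_ms	sweep_001_nA	sweep_002_nA
0	-1.5284765	-1.20121379
1	-1.0495224	-0.844060686
2	-0.787538913	-0.641233906
3	-0.557002626	-0.429938179
4	-0.396902573	-0.288336986
5	-0.298131097	-0.200204762
6	-0.230358779	-0.16839631
7	-0.132480096	-0.0983079746
8	-0.0970040146	-0.115811796
9	-0.113737864	-0.0629082673
10	-0.00656279693	-0.0338191134
11	-0.0189723617	-0.0575458613
12	-0.0426612019	-0.0236125185
13	-0.00164162762	0.0187463242
14	-0.0234444073	0.0410789135
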