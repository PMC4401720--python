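probeset_id	fold_change	p_value	direction
hsa-miR-634_st	2.8	3.0e-3	up
hsa-miR-133b_st	2.8	1.8e-2	up
hsa-miR-133a_st	2.0	2.7e-2	up
hsa-miR-1226-star_st	1.8	3.2e-2	up
hsa-miR-487b_st	1.8	1.3e-2	up
hsa-miR-1260_st	1.6	2.6e-2	up
hsa-miR-550_st	1.5	3.3e-2	up
hsa-miR-1246_st	-3.2	1.0e-3	down
hsa-miR-3201_st	-1.8	3.8e-2	down
hsa-miR-218_st	-1.7	1.1e-2	down
hsa-miR-224-star_st	-1.6	7.4e-3	down
hsa-miR-1975_st	-1.5	1.6e-3	down
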