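probeset_id	fold_change	p_value	direction
hsa-miR-143_st	9.1	1.0e-3	up
hsa-miR-145_st	8.0	1.2e-3	up
hsa-miR-133b_st	6.7	8.9e-5	up
hsa-miR-214_st	5.7	1.6e-3	up
hsa-miR-634_st	5.3	2.0e-5	up
hsa-miR-126_st	5.0	7.6e-4	up
hsa-miR-139-5p_st	4.5	1.6e-4	up
hsa-miR-199a-3p_st	3.9	3.3e-3	up
hsa-miR-199a-5p_st	3.7	9.1e-3	up
hsa-miR-133a_st	3.7	1.9e-4	up
hsa-miR-195_st	2.7	8.9e-4	up
hsa-miR-181c_st	2.7	1.3e-3	up
hsa-miR-675_st	2.6	1.2e-4	up
hsa-miR-127-3p_st	2.3	5.8e-3	up
hsa-let-7b-star_st	2.1	4.2e-3	up
hsa-miR-1260_st	2.1	1.2e-3	up
hsa-miR-1226-star_st	2.1	9.3e-3	up
hsa-miR-636_st	2.0	2.2e-4	up
hsa-miR-193b-star_st	2.0	2.6e-3	up
hsa-miR-487b_st	2.0	4.3e-3	up
hsa-miR-193b_st	1.9	6.6e-3	up
hsa-miR-138-1-star_st	1.8	4.2e-3	up
hsa-miR-181a_st	1.7	5.4e-7	up
hsa-miR-550_st	1.7	8.2e-3	up
hsa-miR-181b_st	1.5	3.1e-4	up
hsa-miR-449b_st	-1.6	3.1e-3	down
hsa-miR-224-star_st	-1.6	4.5e-3	down
hsa-miR-1975_st	-1.8	1.4e-4	down
hsa-miR-1979_st	-1.9	2.1e-4	down
hsa-miR-218_st	-2.0	1.7e-3	down
hsa-miR-146a_st	-2.1	2.9e-3	down
hsa-miR-203_st	-2.1	5.6e-4	down
hsa-miR-3201_st	-2.2	6.3e-3	down
hsa-miR-1246_st	-3.8	2.7e-4	down
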