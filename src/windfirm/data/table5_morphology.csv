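tree_id,species,dbh_cm,crown_base_m,height_m,crown_ew_m,crown_ns_m,avg_crown_width_m
S1,spruce,26.7,3.7,7.8,5.2,5.8,5.5
S2,spruce,34.3,6.6,12.9,7.4,6.9,7.2
S3,spruce,32.8,5.3,9.6,8.3,4.4,6.4
S4,spruce,34.8,6.1,13.4,8.2,8.7,8.5
S5,spruce,37.8,7.0,14.1,7.2,5.0,6.1
S6,spruce,31.7,5.1,8.4,8.2,9.6,8.9
S7,spruce,39.3,6.0,11.8,11.8,12.6,12.2
S8,spruce,37.8,5.5,10.2,11.3,8.2,9.8
S9,spruce,39.8,5.7,11.8,11.2,12.5,11.9
S10,spruce,42.8,6.4,12.0,10.2,8.8,9.5
S11,spruce,47.0,11.6,19.3,12.3,8.3,10.3
S12,spruce,34.1,10.9,17.8,6.3,7.8,7.1
S13,spruce,37.3,12.6,17.4,7.2,4.6,5.9
S14,spruce,35.2,11.9,16.9,5.3,6.2,5.8
S15,spruce,38.5,12.3,15.9,5.8,9.4,7.6
S16,spruce,30.0,8.7,14.9,6.4,8.3,7.4
S17,spruce,26.6,10.6,17.1,2.7,3.1,2.9
S18,spruce,36.8,12.2,18.6,3.3,10.2,6.8
S19,spruce,22.6,10.3,17.6,1.8,4.1,3.0
S20,spruce,36.1,9.7,18.8,8.3,11.5,9.9
K1,korean_pine,25.1,7.3,16.7,4.1,3.7,3.9
K2,korean_pine,27.2,12.6,29.1,5.8,6.7,6.3
K3,korean_pine,64.5,16.5,35.6,8.6,8.7,8.7
K4,korean_pine,22.3,7.7,16.6,6.4,6.4,6.4
K5,korean_pine,46.8,11.8,24.2,4.8,8.3,6.6
K6,korean_pine,91.7,18.3,30.9,12.4,14.6,13.5
K7,korean_pine,34.3,14.6,29.7,8.6,8.2,8.4
K8,korean_pine,50.5,16.8,24.8,7.6,9.8,8.7
K9,korean_pine,52.9,16.2,33.4,12.8,13.6,13.2
K10,korean_pine,72.0,14.9,33.8,9.0,9.6,9.3
K11,korean_pine,90.8,18.9,35.9,14.7,15.9,15.3
K12,korean_pine,68.2,23.7,36.2,11.4,10.2,10.8
K13,korean_pine,26.1,7.2,16.2,4.1,5.6,4.9
K14,korean_pine,25.5,8.4,16.8,7.3,5.6,6.5
K15,korean_pine,27.2,8.9,14.9,5.8,6.4,6.1
K16,korean_pine,24.2,9.4,15.6,2.9,4.7,3.8
K17,korean_pine,28.8,11.4,17.3,6.9,5.2,6.1
K18,korean_pine,26.0,9.4,17.2,9.2,7.9,8.6
K19,korean_pine,26.9,7.1,17.2,8.6,7.8,8.2
K20,korean_pine,27.2,7.9,16.5,8.2,9.6,8.9
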