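tree_id,species,delta_prime,hazard_level,flag
S1,spruce,1.18,High,
S2,spruce,1.01,High,
S3,spruce,5.32,High,label_anomaly
S4,spruce,0.17,High,
S5,spruce,1.51,Low,
S6,spruce,7.84,Low,
S7,spruce,0.98,High,
S8,spruce,2.73,Low,
S9,spruce,1.40,Moderate,
S10,spruce,2.82,Low,
S11,spruce,1.32,Moderate,
S12,spruce,1.65,Low,
S13,spruce,0.70,High,
S14,spruce,0.47,High,
S15,spruce,1.10,High,
S16,spruce,0.33,High,
S17,spruce,2.15,Low,
S18,spruce,0.31,High,
S19,spruce,0.70,High,
S20,spruce,0.43,High,
K1,korean_pine,0.83,High,
K2,korean_pine,0.90,High,
K3,korean_pine,0.71,High,
K4,korean_pine,1.72,Low,
K5,korean_pine,1.13,High,
K6,korean_pine,0.69,High,
K7,korean_pine,0.89,High,
K8,korean_pine,1.13,High,
K9,korean_pine,0.81,High,
K10,korean_pine,0.86,High,
K11,korean_pine,0.77,High,
K12,korean_pine,0.72,High,
K13,korean_pine,1.89,Low,
K14,korean_pine,1.59,Low,
K15,korean_pine,2.39,Low,
K16,korean_pine,1.56,Low,
K17,korean_pine,0.96,High,
K18,korean_pine,1.38,Moderate,
K19,korean_pine,0.69,High,
K20,korean_pine,1.38,Moderate,
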