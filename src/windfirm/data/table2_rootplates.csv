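tree_id,species,volume_m3,coarse_root_mass_kg,soil_mass_kg,total_mass_kg,coarse_root_fraction_pct
S1,spruce,0.28,40.01,310.29,350.30,11.42
S2,spruce,2.00,68.60,2175.40,2243.99,3.06
S3,spruce,1.46,64.73,1592.00,1656.73,3.91
S4,spruce,2.43,73.43,2652.98,2726.41,2.69
S5,spruce,2.44,89.29,2659.25,2748.54,3.25
S6,spruce,1.14,59.35,1246.59,1305.94,4.54
S7,spruce,2.55,105.22,2775.02,2880.24,3.65
S8,spruce,2.55,96.67,2775.02,2871.69,3.37
S9,spruce,3.77,111.02,4104.98,4216.00,2.63
S10,spruce,3.39,132.07,3695.04,3827.11,3.45
S11,spruce,3.81,142.63,4150.04,4292.67,3.32
S12,spruce,1.54,57.17,1675.97,1733.14,3.30
S13,spruce,2.04,70.78,2221.96,2292.75,3.09
S14,spruce,2.15,60.92,2344.52,2405.44,2.53
S15,spruce,2.55,78.24,2775.02,2853.26,2.74
S16,spruce,0.92,42.40,998.06,1040.45,4.07
S17,spruce,0.61,27.98,662.34,690.33,4.05
S18,spruce,2.21,68.78,2412.05,2480.83,2.77
S19,spruce,0.28,17.57,302.04,319.62,5.50
S20,spruce,2.29,70.14,2498.92,2569.06,2.73
K1,korean_pine,0.46,32.96,502.35,535.31,6.16
K2,korean_pine,1.43,40.01,1553.62,1593.64,2.51
K3,korean_pine,3.21,434.70,3504.05,3938.76,11.04
K4,korean_pine,0.30,23.66,322.81,346.46,6.83
K5,korean_pine,2.08,181.46,2265.70,2447.17,7.42
K6,korean_pine,4.18,1149.48,4556.20,5705.68,20.15
K7,korean_pine,1.95,75.64,2125.94,2201.58,3.44
K8,korean_pine,3.05,219.99,3329.27,3549.27,6.20
K9,korean_pine,3.06,250.79,3338.74,3589.53,6.99
K10,korean_pine,4.00,593.40,4360.00,4953.40,11.98
K11,korean_pine,4.16,1116.47,4534.40,5650.87,19.76
K12,korean_pine,3.45,497.85,3760.50,4258.35,11.69
K13,korean_pine,0.99,36.76,1079.50,1116.26,3.29
K14,korean_pine,0.64,34.18,695.34,729.52,4.69
K15,korean_pine,1.45,40.77,1575.18,1615.94,2.52
K16,korean_pine,0.57,29.37,624.60,653.97,4.49
K17,korean_pine,1.85,47.16,2018.83,2065.98,2.28
K18,korean_pine,0.66,35.86,714.07,749.93,4.78
K19,korean_pine,0.67,40.01,733.72,773.73,5.17
K20,korean_pine,1.76,41.03,1919.08,1960.11,2.09
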