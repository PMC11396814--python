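depth_top_cm,depth_bottom_cm,bulk_density_g_cm3,bulk_density_se,porosity_pct,porosity_se,water_content_pct,water_content_se,sand_pct,sand_se,silt_pct,silt_se,clay_pct,clay_se
0,15,1.02,0.13,75.35,2.84,42.53,2.41,34.83,2.56,59.23,2.06,5.94,0.81
15,30,0.92,0.15,79.35,3.17,44.17,2.27,31.36,1.73,63.49,3.18,7.66,1.01
30,45,1.17,0.09,63.93,1.55,37.00,2.84,28.41,1.86,60.73,1.47,10.86,1.18
45,60,1.24,0.18,70.6,1.89,28.13,3.66,30.02,1.22,50.15,1.36,19.83,1.86
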