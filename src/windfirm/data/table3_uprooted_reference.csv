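species,dbh_cm,dbh_pm,height_m,height_pm,crown_base_m,crown_base_pm,crown_width_m,crown_width_pm,volume_m3,volume_pm,mass_kg,mass_pm,flag
spruce,28.60,14.50,19.73,8.18,11.15,0.65,6.54,1.66,4.24,1.72,3407.56,137.51,
korean_pine,45.18,11.90,24.30,5.14,12.39,0.62,7.71,2.04,10.02,2.04,1624.99,248.14,volume_mass_suspect
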