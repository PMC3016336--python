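compound,molecular_weight_g_mol,kow,vapor_pressure_pa,henry_constant_pa_m3_mol,koc_l_kg,half_life_soil_d,half_life_water_d,half_life_sediment_d,mdl_survey_2007_ng_g,mdl_survey_2008_ng_g,lc50_10d_ng_g
bifenthrin,422.9,2.00e7,1.78e-5,7.74e-5,2.37e5,85,8,251,2.2,0.5,5.2
lambda-cyhalothrin,449.85,7.94e6,2.00e-7,2.00e-2,1.57e5,25,8,12,2.4,2.0,4.5
esfenvalerate,419.9,1.74e6,1.20e-9,4.90e-4,5300,44,30,71,2.1,1.0,15.4
permethrin,391.3,1.26e6,2.00e-6,1.89e-1,1.00e5,42,23,40,1.0,2.0,108
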