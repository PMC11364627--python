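type_id,climate_change_mean,climate_change_sd,exploitation_mean,exploitation_sd,invasive_species_mean,invasive_species_sd,habitat_loss_mean,habitat_loss_sd,pollution_mean,pollution_sd,discrimination_mean,discrimination_sd
1,1.68,0.82,4.94,0.24,4.37,1.23,4.95,0.22,4.14,1.19,1.18,1.07
2,4.69,0.57,4.88,0.35,4.66,0.66,4.89,0.33,3.20,0.91,1.92,0.75
3,2.70,1.37,2.55,1.18,2.50,1.24,2.69,1.21,2.64,1.31,-0.33,0.94
4,4.22,0.76,3.69,1.00,3.44,0.86,3.95,0.86,4.04,0.86,0.76,0.77
5,4.80,0.48,4.80,0.49,4.86,0.35,4.80,0.45,4.79,0.46,0.89,0.70
6,4.90,0.38,4.88,0.35,4.28,0.69,4.97,0.16,4.74,0.44,2.37,0.80
7,4.78,0.50,4.79,0.46,1.33,0.47,4.88,0.32,4.40,1.06,1.08,1.04
8,4.90,0.28,4.87,0.31,3.57,0.57,4.87,0.37,4.70,0.47,0.75,0.51
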