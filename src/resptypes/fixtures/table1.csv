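country,n,climate_change_mean,climate_change_sd,exploitation_mean,exploitation_sd,invasive_species_mean,invasive_species_sd,habitat_loss_mean,habitat_loss_sd,pollution_mean,pollution_sd
AUS,103,4.67,0.83,4.75,0.72,4.50,0.71,4.80,0.51,4.25,0.80
BRA,96,4.92,0.31,4.94,0.56,4.58,0.95,4.96,0.54,4.63,0.68
CAN,190,4.62,0.99,4.81,0.61,4.19,1.17,4.77,0.74,4.38,0.85
CHN,105,4.38,0.97,4.61,0.78,3.94,1.11,4.57,0.85,4.44,0.93
COL,119,4.89,0.85,4.58,1.18,4.23,1.25,4.81,0.92,4.66,0.93
CRC,30,4.93,0.25,4.90,0.30,4.43,0.92,4.90,0.93,4.41,1.12
DOM,112,4.84,1.29,4.70,1.13,4.32,1.47,4.84,1.19,4.54,1.16
ECU,29,4.93,0.25,4.86,0.43,4.61,1.19,4.93,0.25,4.59,0.93
ESP,294,4.79,1.04,4.67,0.93,4.27,0.99,4.73,0.78,4.57,0.86
FRA,115,4.66,1.02,4.79,0.98,4.18,1.20,4.80,0.90,4.46,0.96
GBR,97,4.76,0.77,4.76,0.47,3.80,1.04,4.66,0.69,4.34,0.77
GER,340,4.43,1.08,4.32,1.01,4.02,1.02,4.42,0.90,4.26,0.95
IND,57,4.77,0.73,4.77,0.53,4.04,1.20,4.77,0.84,4.23,1.20
IRL,74,4.81,0.68,4.82,0.45,3.88,1.14,4.75,0.82,4.54,0.66
JPN,59,4.33,1.03,4.43,0.97,3.86,1.27,4.31,0.89,4.34,0.73
KEN,61,4.83,0.95,4.70,1.03,3.68,1.72,4.86,0.96,4.49,1.10
KOR,48,4.56,0.61,4.65,0.48,4.02,0.78,4.54,0.61,4.40,0.73
KSA,120,3.72,1.78,4.56,1.38,3.82,1.64,4.52,1.46,4.03,1.65
MAR,43,4.48,1.22,4.32,1.51,3.56,1.73,4.63,1.35,4.26,1.51
MEX,159,4.82,0.95,4.81,0.52,4.60,0.84,4.83,0.53,4.58,0.73
NGR,85,4.60,1.10,4.61,1.08,3.30,1.62,4.71,0.89,4.52,1.26
PAK,101,4.78,0.78,4.55,0.99,3.73,1.33,4.61,0.88,4.30,1.13
PAN,28,4.89,0.41,4.82,0.54,4.64,1.04,4.93,0.37,5.00,0.93
PER,122,4.48,1.23,4.45,0.86,3.99,1.18,4.52,0.88,4.45,0.96
PHI,264,4.74,0.93,4.55,1.19,3.95,1.54,4.66,1.16,4.44,1.19
POL,502,4.53,1.04,4.41,0.99,4.22,1.09,4.45,0.91,4.29,0.98
POR,204,4.71,0.73,4.69,0.64,4.44,0.94,4.78,0.47,4.27,0.82
PUR,56,4.89,0.74,4.84,0.45,3.59,1.25,4.95,0.29,4.66,0.61
RSA,30,4.57,0.62,4.77,0.76,4.50,0.72,4.80,0.48,4.43,0.76
RUS,102,3.88,1.10,4.29,1.12,3.96,1.15,4.48,0.92,4.10,1.07
SGP,127,4.65,0.73,4.76,0.68,3.61,1.23,4.70,0.69,4.48,0.82
SVK,131,4.53,0.97,4.37,1.01,3.74,1.26,4.65,0.82,4.32,0.90
SWE,49,4.55,0.67,4.94,0.74,4.22,1.02,4.92,0.34,4.14,0.95
THA,66,4.54,1.08,3.70,1.50,4.15,1.24,4.58,1.14,4.09,1.32
TPE,182,4.44,1.00,4.62,0.91,4.02,1.16,4.49,0.97,4.42,0.99
UAE,60,4.54,0.96,4.47,0.74,4.07,1.11,4.75,0.54,4.37,0.87
USA,81,4.61,0.86,4.62,0.70,4.09,1.00,4.53,0.89,4.33,0.83
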