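type_id,CO2_r,CO2_p,EPI_r,EPI_p,GBI_r,GBI_p,NIS_r,NIS_p,LPI_r,LPI_p
1,0.458,0.005,-0.194,0.257,-0.149,0.393,0.112,0.511,-0.033,0.850
2,0.166,0.326,0.389,0.019,-0.306,0.074,0.377,0.022,0.367,0.028
3,0.171,0.313,-0.445,0.006,-0.011,0.949,-0.176,0.298,-0.369,0.027
4,0.399,0.014,-0.001,0.997,-0.155,0.373,0.089,0.599,0.121,0.482
5,-0.149,0.380,-0.180,0.292,0.468,0.005,-0.088,0.603,-0.323,0.055
6,0.177,0.296,0.346,0.039,0.012,0.944,0.339,0.040,0.487,0.003
7,-0.402,0.014,-0.329,0.050,-0.170,0.329,-0.516,0.001,-0.334,0.047
8,-0.249,0.138,0.074,0.666,-0.253,0.142,-0.060,0.723,0.101,0.557
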