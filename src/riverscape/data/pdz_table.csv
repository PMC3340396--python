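pdz,length_km,channel_length_km,width_km,water_area_km2,landmark_area_km2,n_water_masses,n_tributaries,volume_km3,watershed_area_km2,wetland_area_km2,printed_mean_depth_m,printed_cumulated_watershed_km2,printed_confluence_density,printed_wetland_pct,printed_photic_pct,density_reproducible
LSF,50,50,4.7,225.4,259.56,2,3,1.12,772000,20.43,4.97,772000,0.06,9.06,100,True
LSL,26,26,6.5,136.31,151.51,3,3,0.62,148843,6.85,4.55,920843,0.13,5.03,60.32,False
FR,104,104,4.3,131.6,253.24,4,2,0.71,319940,12.01,5.4,1240783,0.025,9.12,57.70,False
LSP,35,35,15,241.02,315.58,8,5,0.75,21127,160.98,3.11,1261910,0.143,66.79,63.06,True
FE,182,182,3.2,472.38,640.32,10,9,4.23,68245,29.99,8.95,1330155,0.049,6.35,28.38,True
ETZ,58,58,22,1341.33,1521.37,2,1,14.96,2328,32.79,11.15,1332483,0.001,2.44,16.95,False
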