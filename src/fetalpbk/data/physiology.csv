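species,stage,organ,volume_L,blood_flow_L_per_min,surface_area_dm2,is_fetal
rat,,arterial,0.0062,0,0,0
rat,,venous,0.0123,0,0,0
rat,,gut_lumen,0.010,0,0,0
rat,,gut_tissue,0.0068,0.0127,10,0
rat,,liver,0.0086,0.00174,10,0
rat,,brain,0.0014,0.00166,2.5,0
rat,,fat,0.0175,0.00581,3,0
rat,,muscle,0.101,0.0231,30,0
rat,,kidney,0.0018,0.0117,3.5,0
rat,,rest_of_body,0.080,0.0263,30,0
human,,arterial,1.7,0,0,0
human,,venous,3.5,0,0,0
human,,gut_lumen,0.25,0,0,0
human,,gut_tissue,1.10,0.90,350,0
human,,liver,1.80,0.35,500,0
human,,brain,1.45,0.70,1500,0
human,,fat,15.0,0.30,400,0
human,,muscle,28.0,1.05,3000,0
human,,kidney,0.31,1.10,120,0
human,,rest_of_body,8.0,1.20,2000,0
human,gw20,arterial,1.7,0,0,0
human,gw20,venous,3.5,0,0,0
human,gw20,gut_lumen,0.25,0,0,0
human,gw20,gut_tissue,1.10,0.95,350,0
human,gw20,liver,1.80,0.35,500,0
human,gw20,brain,1.45,0.70,1500,0
human,gw20,fat,15.0,0.30,400,0
human,gw20,muscle,28.0,1.05,3000,0
human,gw20,kidney,0.31,1.20,120,0
human,gw20,rest_of_body,8.0,1.25,2000,0
human,gw20,placenta,0.25,0.35,150,0
human,gw20,fetal_plasma,0.025,0,0,1
human,gw20,fetal_tissue,0.30,0,50,1
human,gw40,arterial,1.7,0,0,0
human,gw40,venous,3.5,0,0,0
human,gw40,gut_lumen,0.25,0,0,0
human,gw40,gut_tissue,1.10,1.00,350,0
human,gw40,liver,1.80,0.35,500,0
human,gw40,brain,1.45,0.70,1500,0
human,gw40,fat,15.0,0.30,400,0
human,gw40,muscle,28.0,1.05,3000,0
human,gw40,kidney,0.31,1.25,120,0
human,gw40,rest_of_body,8.0,1.30,2000,0
human,gw40,placenta,0.55,0.60,500,0
human,gw40,fetal_plasma,0.28,0,0,1
human,gw40,fetal_tissue,3.2,0,200,1
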