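,Outside_temp,Outside_humidity,Carcass_in_the_day,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp
Outside_temp,1.5558,-0.2888,-0.9338,0.2044,0.0245,0.5703,0.0407,0.7736
Outside_humidity,-0.2888,1.2188,0.1059,0.2422,0.0378,0.0110,0.3646,0.0897
Carcass_in_the_day,-0.9338,0.1059,8.1871,-0.2024,5.8989,-1.5891,0.1647,-1.1433
Loading_completion,0.2044,0.2422,-0.2024,1.2093,-0.1780,-0.1249,0.3276,0.0878
Preset_temp,0.0245,0.0378,5.8989,-0.1780,6.5947,-0.5270,-0.3142,0.4740
Room_temp_at_16_30,0.5703,0.0110,-1.5891,-0.1249,-0.5270,1.7720,0.2327,0.3401
Room_temp_next_8_00,0.0407,0.3646,0.1647,0.3276,-0.3142,0.2327,1.5017,0.1131
Surface_temp,0.7736,0.0897,-1.1433,0.0878,0.4740,0.3401,0.1131,2.1392
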