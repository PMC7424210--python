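,Outside_temp,Outside_humidity,Carcass_in_the_day,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp
Outside_temp,1,0.3059,0.0976,-0.2262,-0.1004,-0.2297,-0.0291,-0.2527
Outside_humidity,0.3059,1,0.0253,-0.1984,-0.0422,-0.0626,-0.2021,-0.1009
Carcass_in_the_day,0.0976,0.0253,1,0.1498,-0.9156,0.5443,-0.4748,0.6334
Loading_completion,-0.2262,-0.1984,0.1498,1,-0.1055,0.2565,-0.2515,0.1250
Preset_temp,-0.1004,-0.0422,-0.9156,-0.1055,1,-0.4395,0.4607,-0.6230
Room_temp_at_16_30,-0.2297,-0.0626,0.5443,0.2565,-0.4395,1,-0.3656,0.3238
Room_temp_next_8_00,-0.0291,-0.2021,-0.4748,-0.2515,0.4607,-0.3656,1,-0.3213
Surface_temp,-0.2527,-0.1009,0.6334,0.1250,-0.6230,0.3238,-0.3213,1
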