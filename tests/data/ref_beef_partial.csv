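,Outside_temp,Outside_humidity,Carcass_in_the_day,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp
Outside_temp,,0.2097,0.2616,-0.1490,-0.0076,-0.3435,-0.0266,-0.4240
Outside_humidity,0.2097,,-0.0335,-0.1995,-0.0133,-0.0075,-0.2695,-0.0556
Carcass_in_the_day,0.2616,-0.0335,,0.0643,-0.8028,0.4172,-0.0470,0.2732
Loading_completion,-0.1490,-0.1995,0.0643,,0.0630,0.0853,-0.2431,-0.0546
Preset_temp,-0.0076,-0.0133,-0.8028,0.0630,,0.1542,0.0998,-0.1262
Room_temp_at_16_30,-0.3435,-0.0075,0.4172,0.0853,0.1542,,-0.1427,-0.1747
Room_temp_next_8_00,-0.0266,-0.2695,-0.0470,-0.2431,0.0998,-0.1427,,-0.0631
Surface_temp,-0.4240,-0.0556,0.2732,-0.0546,-0.1262,-0.1747,-0.0631,
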