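,Outside_temp,Outside_humidity,Carcass_in_the_day,Carcass_after_noon,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp,Core_temp
Outside_temp,,0.2032,-0.0264,0.0856,-0.0752,-0.0479,-0.1727,0.0392,-0.3852,0.0774
Outside_humidity,0.2032,,0.0696,-0.0560,0.3113,0.1612,-0.1925,0.1681,-0.3583,0.3552
Carcass_in_the_day,-0.0264,0.0696,,-0.1088,-0.0478,-0.5946,0.2109,-0.0861,-0.1757,0.0458
Carcass_after_noon,0.0856,-0.0560,-0.1088,,0.4542,-0.2601,0.2620,0.0034,-0.1601,0.2383
Loading_completion,-0.0752,0.3113,-0.0478,0.4542,,-0.2187,0.2890,0.0574,0.1460,-0.1338
Preset_temp,-0.0479,0.1612,-0.5946,-0.2601,-0.2187,,0.1769,0.4715,-0.1202,-0.0120
Room_temp_at_16_30,-0.1727,-0.1925,0.2109,0.2620,0.2890,0.1769,,0.0251,-0.2497,0.2009
Room_temp_next_8_00,0.0392,0.1681,-0.0861,0.0034,0.0574,0.4715,0.0251,,0.1291,-0.2308
Surface_temp,-0.3852,-0.3583,-0.1757,-0.1601,0.1460,-0.1202,-0.2497,0.1291,,0.5239
Core_temp,0.0774,0.3552,0.0458,0.2383,-0.1338,-0.0120,0.2009,-0.2308,0.5239,
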