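,Outside_temp,Outside_humidity,Carcass_in_the_day,Carcass_after_noon,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp,Core_temp
Outside_temp,1.4772,-0.3198,0.0600,-0.1918,0.1536,0.1425,0.3024,-0.0830,0.6781,-0.1355
Outside_humidity,-0.3198,1.6767,-0.1682,0.1337,-0.6778,-0.5110,0.3592,-0.3794,0.6720,-0.6630
Carcass_in_the_day,0.0600,-0.1682,3.4787,0.3741,0.1501,2.7154,-0.5666,0.2799,0.4746,-0.1231
Carcass_after_noon,-0.1918,0.1337,0.3741,3.3983,-1.4082,1.1741,-0.6959,-0.0110,0.4276,-0.6333
Loading_completion,0.1536,-0.6778,0.1501,-1.4082,2.8281,0.9005,-0.7002,-0.1682,-0.3557,0.3244
Preset_temp,0.1425,-0.5110,2.7154,1.1741,0.9005,5.9950,-0.6242,-2.0120,0.4262,0.0425
Room_temp_at_16_30,0.3024,0.3592,-0.5666,-0.6959,-0.7002,-0.6242,2.0758,-0.0630,0.5212,-0.4171
Room_temp_next_8_00,-0.0830,-0.3794,0.2799,-0.0110,-0.1682,-2.0120,-0.0630,3.0368,-0.3257,0.5796
Surface_temp,0.6781,0.6720,0.4746,0.4276,-0.3557,0.4262,0.5212,-0.3257,2.0981,-1.0937
Core_temp,-0.1355,-0.6630,-0.1231,-0.6333,0.3244,0.0425,-0.4171,0.5796,-1.0937,2.0775
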