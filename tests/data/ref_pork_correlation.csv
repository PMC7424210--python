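,Outside_temp,Outside_humidity,Carcass_in_the_day,Carcass_after_noon,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp,Core_temp
Outside_temp,1,0.3892,-0.0157,0.0254,-0.0386,0.0719,-0.0956,0.0877,-0.4842,-0.0978
Outside_humidity,0.3892,1,-0.0683,0.0491,0.1453,0.1702,-0.0166,0.2089,-0.3783,0.0685
Carcass_in_the_day,-0.0157,-0.0683,1,0.5535,0.4880,-0.8188,0.4692,-0.6878,-0.0844,0.3874
Carcass_after_noon,0.0254,0.0491,0.5535,1,0.7496,-0.6653,0.6274,-0.5274,-0.0758,0.4847
Loading_completion,-0.0386,0.1453,0.4880,0.7496,1,-0.5847,0.5963,-0.4201,-0.0233,0.3818
Preset_temp,0.0719,0.1702,-0.8188,-0.6653,-0.5847,1,-0.4351,0.7993,-0.0718,-0.4696
Room_temp_at_16_30,-0.0956,-0.0166,0.4692,0.6274,0.5963,-0.4351,1,-0.3621,-0.1259,0.3588
Room_temp_next_8_00,0.0877,0.2089,-0.6878,-0.5274,-0.4201,0.7993,-0.3621,1,-0.0628,-0.4646
Surface_temp,-0.4842,-0.3783,-0.0844,-0.0758,-0.0233,-0.0718,-0.1259,-0.0628,1,0.3434
Core_temp,-0.0978,0.0685,0.3874,0.4847,0.3818,-0.4696,0.3588,-0.4646,0.3434,1
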