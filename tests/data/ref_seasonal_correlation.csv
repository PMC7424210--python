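,Electric_consumption,Operating_days,Outside_temperature,Carcass_volume
Electric_consumption,1,0.2332,0.9307,-0.5181
Operating_days,0.2332,1,0.0172,0.2021
Outside_temperature,0.9307,0.0172,1,-0.7063
Carcass_volume,-0.5181,0.2021,-0.7063,1
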