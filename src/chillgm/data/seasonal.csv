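month,Electric_consumption,Operating_days,Outside_temperature,Beef_carcass,Pork_carcass,Carcass_volume
Apr 2016,84330,21,23.3,746,17024,20008
May 2016,76720,19,29.0,740,14802,17762
Jun 2016,87300,20,29.5,621,14677,17161
Jul 2016,93850,20,33.5,718,14367,17239
Aug 2016,98770,21,35.3,767,15417,18485
Sep 2016,96240,20,34.4,653,16142,18754
Oct 2016,84140,20,29.4,792,16337,19505
Nov 2016,76960,20,21.5,828,17912,21224
Dec 2016,73540,20,19.6,756,17038,20062
Jan 2017,63200,19,13.1,752,17339,20347
Feb 2017,63770,20,18.3,635,16473,19013
Mar 2017,72060,22,17.5,680,17438,20158
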