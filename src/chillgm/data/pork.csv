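sample_id,Outside_temp,Outside_humidity,Carcass_in_the_day,Carcass_after_noon,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp,Core_temp
PC20160404,18,86,110,0,12.58,-2.7,-3.8,-2.1,-2.8,0.1
PC20160411,17,34,115,18,14.50,-2.8,-2.9,-2.2,-0.4,-0.1
PC20160421,18,81,169,95,15.83,-3.2,2.6,-3.7,1.2,1.0
PC20160426,21,51,242,20,15.58,-4.2,0.4,-4.0,1.3,0.5
PC20160505,23,29,262,88,16.00,-4.7,3.1,-4.8,-2.5,0.2
PC20160510,20,77,229,30,15.50,-3.2,1.7,-3.7,-4.9,-0.1
PC20160523,25,44,119,0,12.42,-2.7,-2.8,-3.5,-7.1,-0.5
PC20160530,21,80,113,0,12.58,-2.7,-2.2,-3.0,-4.7,-0.3
PC20160607,22,67,165,31,14.50,-2.8,0.9,-2.9,-4.6,0.3
PC20160620,25,75,214,33,13.83,-3.2,1.3,-3.4,-5.2,0.3
PC20160708,27,71,201,95,16.00,-3.3,3.9,-2.0,-6.4,0.0
PC20160711,28,54,211,0,13.00,-3.1,-0.8,-3.4,-4.3,-0.2
PC20160719,29,61,217,90,15.67,-3.3,4.7,-3.6,-5.1,0.4
PC20160726,25,76,186,28,14.67,-3.1,1.5,-3.1,-4.8,-0.7
PC20160801,30,50,210,0,12.50,-3.1,0.3,-2.8,-5.7,-0.6
PC20160808,31,54,109,18,14.00,-2.8,2.3,-2.9,-3.8,0.5
PC20160816,28,62,220,76,15.17,-3.3,0.8,-3.7,-3.7,0.1
PC20160830,27,46,163,36,14.50,-2.8,2.3,-3.0,-5.1,-0.7
PC20160905,27,86,109,19,14.33,-2.3,1.7,-2.7,-5.1,-0.2
PC20160913,26,86,170,57,15.17,-3.2,4.0,-3.4,-4.9,-0.5
PC20160920,24,78,228,63,16.17,-3.7,-3.3,-4.0,-6.1,-0.3
PC20160926,25,77,124,28,14.50,-2.8,3.2,-2.8,-5.1,-0.4
PC20161011,23,50,234,130,15.33,-3.8,5.8,-3.6,-5.3,0.2
PC20161017,21,81,137,38,15.92,-2.8,1.8,-2.5,-5.5,-0.2
PC20161025,19,63,200,103,15.08,-3.3,5.0,-3.6,-4.3,0.1
PC20161102,17,43,258,113,15.92,-4.1,2.1,-4.1,-2.2,0.0
PC20161107,17,43,115,27,14.75,-2.8,2.4,-3.0,-2.3,0.1
PC20161114,17,63,155,17,14.42,-2.8,-0.3,-2.7,-2.7,-0.5
PC20161121,18,63,233,56,15.25,-4.3,5.3,-4.0,-2.7,0.2
PC20161128,15,35,132,0,12.42,-2.7,-1.4,-3.6,-0.3,-0.4
PC20161206,16,40,165,62,14.92,-3.1,2.6,-3.6,-2.1,0.0
PC20161213,11,66,229,103,15.83,-3.8,3.4,-3.3,-5.0,-0.1
PC20161219,13,48,154,43,15.17,-2.8,3,-2.2,-0.8,-0.2
PC20160104,12,46,199,68,16.17,-3.2,4.8,-4.1,-4.3,0.2
PC20160111,12,41,228,84,16.00,-3.8,5.3,-3.9,-3.5,0.1
PC20160116,7,48,154,38,15.08,-2.8,4.3,-3.1,-2.3,-0.1
PC20160123,8,43,127,14,14.50,-2.7,1.4,-2.6,-3.3,-0.7
PC20160206,10,51,236,0,12.67,-3.2,3.6,-3.3,-3.2,0.2
PC20160213,9,40,144,0,12.58,-2.8,-2.3,-2.8,-2.1,-0.4
PC20160227,12,36,126,0,12.67,-2.7,-2.2,-2.8,-0.4,0.0
PC20160306,12,69,234,0,15.83,-3.2,2.5,-3.4,-3.5,0.4
PC20160314,14,37,196,52,16.00,-4.3,3.1,-4.4,-4.5,-0.2
PC20160321,13,60,261,154,16.33,-4.8,4.9,-5.4,-2.9,1.3
PC20160327,13,39,214,0,12.67,-3.1,2.7,-3.5,-3.6,-0.1
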