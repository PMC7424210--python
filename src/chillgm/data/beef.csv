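sample_id,Outside_temp,Outside_humidity,Carcass_in_the_day,Loading_completion,Preset_temp,Room_temp_at_16_30,Room_temp_next_8_00,Surface_temp
BC20160404,18,86,40,11.67,-6.2,1.0,-5.1,6.1
BC20160411,17,34,44,12.08,-6.7,1.1,-4.4,6.8
BC20160419,19,33,47,11.83,-7.2,1.4,-3.2,6.7
BC20160509,20,68,50,12.17,-7.2,5.4,-6.0,6.3
BC20160523,25,44,44,11.75,-6.7,4.1,-6.2,6.3
BC20160530,21,80,50,11.50,-7.2,4.8,-7.1,7.1
BC20160606,22,58,43,11.92,-6.7,4.6,-6.0,5.7
BC20160620,25,75,39,11.83,-6.2,3.8,-6.5,3.6
BC20160621,24,77,40,11.33,-6.2,3.4,-6.2,3.1
BC20160627,25,52,49,12.67,-5.7,4.3,-7.1,5.5
BC20160704,30,61,49,12.08,-7.2,3.5,-6.7,7.9
BC20160711,28,54,47,11.83,-7.2,2.7,-6.9,7.7
BC20160719,29,61,51,12.67,-7.7,3.5,-8.3,5.7
BC20160725,27,54,48,11.58,-7.2,3.7,-7.2,6.3
BC20160801,30,50,51,12.42,-7.7,4.3,-6.7,5.6
BC20160808,31,54,16,11.92,-4.2,-0.3,-3.5,3.2
BC20160816,28,62,51,11.67,-7.7,3.1,-8.1,6.9
BC20160823,29,65,44,12.67,-6.7,2.3,-7.5,6.4
BC20160829,31,45,50,12.17,-7.2,2.7,-6.4,5.3
BC20160906,27,76,50,11.33,-7.2,3.4,-5.1,6.6
BC20160912,27,68,42,11.75,-6.7,2.9,-7.4,4.4
BC20160926,25,77,43,12.42,-6.7,2.4,-7.8,6.4
BC20161003,25,84,49,11.83,-7.2,4.9,-6.5,7.3
BC20161011,23,50,48,11.92,-7.2,6.2,-6.5,5.6
BC20161017,21,81,44,12.67,-6.7,6.5,-6.6,5.9
BC20161024,21,39,44,12.00,-6.7,5.0,-5.9,6.1
BC20161031,19,50,40,12.25,-6.2,4.3,-7.1,4.8
BC20161101,19,49,40,12.50,-6.2,4.1,-5.7,5.6
BC20161107,17,43,48,12.42,-7.2,6.5,-7.1,7.3
BC20161114,17,63,47,12.33,-7.2,2.3,-7.4,7.6
BC20161128,15,35,50,12.58,-7.2,5.6,-6.6,7.3
BC20161205,16,49,50,11.83,-7.2,5.8,-8.8,8.7
BC20161212,11,36,50,12.25,-7.2,5.0,-7.5,8.9
BC20161219,13,48,27,12.00,-5.2,-1.0,-6.2,4.4
BC20160110,12,46,49,12.92,-7.2,5.0,-6.9,7.3
BC20160116,7,48,44,12.50,-6.7,5.0,-6.1,5.5
BC20160123,8,43,34,11.75,-5.7,4.0,-5.9,5.3
BC20160130,11,72,45,12.08,-6.7,5.0,-6.4,8.5
BC20160206,10,51,42,12.75,-6.7,5.1,-6.4,6.4
BC20160227,12,36,40,12.00,-6.2,4.3,-6.1,5.3
BC20160306,12,69,46,13.00,-7.2,4.0,-7.3,6.1
BC20160313,12,61,41,11.67,-6.7,2.3,-6.9,6.7
BC20160321,13,60,48,12.08,-7.2,3.2,-7.7,6.8
BC20160327,13,39,45,12.00,-6.7,5.3,-6.0,6.4
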