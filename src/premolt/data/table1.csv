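bird_id,sex,body_mass_kg,trip_start,trip_end,duration_days,landfall_location,trip_length_km,max_range_km,destination,reversal_date,outward_days,inbound_days,daily_dist_median_km,daily_dist_min_km,daily_dist_max_km,status
F45,female,2.50,2016-12-18,2017-02-22,66,GR,5381,1973,SAF,2017-01-26,39,23,69.7,0.7,222.8,complete
M49,male,3.60,2016-12-05,2017-02-20,77,GR,5597,2252,SAF,2017-01-16,42,35,68.9,1.8,180.5,complete
F50,female,2.90,2016-11-19,2017-02-01,74,GR,4459,1617,STF,2016-12-27,38,36,64.4,4.2,178.8,complete
M42,male,3.05,2016-11-22,2017-01-27,66,SS,3505,1371,STF,2017-01-01,40,26,54.8,1.3,122.9,complete
F48,female,2.95,2016-12-03,2017-02-08,67,DS,6801,2288,SAF,2017-01-08,36,31,83.0,5.0,215.8,complete
M44,male,3.40,2016-12-13,2017-02-02,51,,4870,2440,SAF,2017-01-24,42,,69.9,1.0,222.8,inbound_incomplete
M46,male,3.85,2016-12-05,2017-01-22,48,,3448,1564,STF,2016-12-28,23,,70.9,3.7,139.1,inbound_incomplete
M52,male,3.95,2016-12-01,2017-01-18,48,,4244,2245,SAF,2017-01-06,36,,78.4,3.1,225.4,inbound_incomplete
F60,female,2.90,2016-12-01,2017-01-11,41,,2993,1392,STF,2016-12-27,26,,58.7,1.3,122.4,inbound_incomplete
F47,female,3.00,2016-11-30,2016-12-08,8,,473,364,,,,,36.2,7.1,89.1,outward_incomplete
M51,male,3.20,2016-12-01,2016-12-28,27,,1798,1594,,,,,61.3,2.3,134.9,outward_incomplete
F53,female,2.65,2016-12-01,2016-12-03,2,,154,153,,,,,14.7,3.8,63.7,outward_incomplete
M54,male,3.45,2016-12-06,2016-12-26,20,,1420,1167,,,,,47.9,3.4,131.7,outward_incomplete
M56,male,3.40,2016-12-11,2016-12-21,10,,927,828,,,,,59.5,0.4,142.0,outward_incomplete
M58,male,3.00,2016-12-04,2016-12-19,15,,1121,888,,,,,62.3,1.0,172.8,outward_incomplete
M59,male,3.25,2016-11-12,2017-01-06,55,,2686,1280,,,,,49.6,3.1,101.2,outward_incomplete
F61,female,2.95,2016-12-11,2017-01-01,21,,2057,1635,,,,,76.2,2.0,177.3,outward_incomplete
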