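# Projected service-use costs in GBP millions at constant 2016/17 prices,
# England 2025-2040, by sector and group (fit vs frail)
year,primary_fit,primary_frail,primary_total,secondary_fit,secondary_frail,secondary_total,all_fit,all_frail,all_total
2025,1430.9,8910.0,10340.9,3607.5,36818.6,40426.1,5038.4,45728.6,50767.0
2026,1401.4,9088.4,10489.9,3533.1,37696.0,41229.1,4934.6,46784.4,51719.0
2027,1373.0,9252.6,10625.5,3459.9,38508.2,41968.1,4832.9,47760.8,52593.6
2028,1345.2,9403.1,10748.3,3387.3,39254.3,42641.7,4732.5,48657.4,53390.0
2029,1318.3,9540.3,10858.6,3319.1,39954.0,43273.1,4637.4,49494.3,54131.6
2030,1295.5,9666.2,10961.8,3263.1,40617.7,43880.7,4558.6,50283.9,54842.5
2031,1280.9,9784.7,11065.6,3226.2,41248.7,44474.9,4507.0,51033.4,55540.5
2032,1270.7,9895.9,11166.6,3198.4,41835.7,45034.1,4469.1,51731.7,56200.8
2033,1260.8,9998.6,11259.4,3172.6,42385.9,45558.5,4433.4,52384.5,56817.9
2034,1250.5,10090.4,11340.9,3151.1,42924.4,46075.5,4401.5,53014.9,57416.4
2035,1240.5,10173.8,11414.2,3127.5,43400.0,46527.3,4367.9,53573.6,57941.5
2036,1229.8,10249.3,11479.0,3100.4,43822.4,46922.8,4330.2,54071.7,58401.9
2037,1222.1,10320.5,11542.6,3080.1,44213.8,47293.9,4302.2,54534.3,58836.5
2038,1214.2,10387.0,11601.2,3059.5,44576.7,47636.2,4273.7,54963.7,59237.4
2039,1205.0,10448.5,11653.5,3036.1,44913.9,47950.0,4241.1,55362.3,59603.4
2040,1197.9,10507.4,11705.4,3017.6,45238.1,48255.6,4215.5,55745.5,59961.0
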