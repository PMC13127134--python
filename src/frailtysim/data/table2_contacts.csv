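# Projected service-use contacts in millions, England 2025-2040, by sector
# (primary = GP face-to-face/home visit/telephone/e-consultation; secondary &
# urgent = outpatient/ED/elective/unplanned/critical care) and group (fit vs frail)
year,primary_fit,primary_frail,primary_total,secondary_fit,secondary_frail,secondary_total
2025,37.4,225.1,262.5,12.8,94.3,107.1
2026,36.7,229.5,266.2,12.6,96.3,108.9
2027,35.9,233.6,269.5,12.3,98.2,110.5
2028,35.2,237.4,272.6,12.1,100.0,112.1
2029,34.5,240.8,275.3,11.8,101.6,113.4
2030,33.9,243.8,277.7,11.6,103.1,114.7
2031,33.5,246.7,280.2,11.5,104.4,115.9
2032,33.2,249.4,282.6,11.4,105.7,117.1
2033,33.0,251.9,284.9,11.3,106.8,118.1
2034,32.7,254.1,286.8,11.2,107.8,119.0
2035,32.4,256.1,288.5,11.1,108.7,119.8
2036,32.2,257.9,290.1,11.0,109.5,120.5
2037,32.0,259.6,291.6,10.9,110.3,121.2
2038,31.8,261.3,293.1,10.9,111.1,122.0
2039,31.5,262.8,294.3,10.8,111.8,122.6
2040,31.3,264.2,295.5,10.7,112.5,123.2
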