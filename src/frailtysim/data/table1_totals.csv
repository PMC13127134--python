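# Printed column totals of the incidence table (carried exactly as printed; the
# 65-74 total 2509209 exceeds the rounded annual sum 2509200 because totals were
# evidently computed before rounding - kept as printed, not recomputed)
column,total
50-64,5620000
65-74,2509209
75-84,1429900
85+,447600
overall,10006500
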