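# Projected incidence: new cases of frailty per annum, England 2025-2040, persons (values as printed, rounded to 100)
year,50-64,65-74,75-84,85+,overall
2025,400200,160300,105400,31100,696900
2026,390800,158500,103000,30100,682400
2027,380700,158100,100300,28900,667900
2028,370200,158500,97300,27800,653800
2029,360200,159100,94300,27400,641000
2030,352800,159700,91500,27400,631300
2031,348400,160100,88800,27300,624600
2032,345100,160400,86500,27100,619200
2033,341900,160100,84200,27900,614100
2034,338700,159300,82400,28800,609200
2035,335800,158000,81600,28800,604200
2036,333300,156700,81400,28300,599700
2037,331500,155100,81900,27600,596000
2038,330100,152300,82800,26900,592200
2039,329900,148600,83800,26300,588600
2040,330400,144400,84700,25900,585400
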