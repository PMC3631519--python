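trait	category	term	effect_allele	beta
hair	brown_light_brown	(intercept)		0.5387076360380952
hair	brown_light_brown	rs11547464	A	3.158769645313703
hair	brown_light_brown	rs885479	A	-0.3050332744214126
hair	brown_light_brown	rs1805008	A	-0.8212080421169433
hair	brown_light_brown	rs1805005	A	-0.34087502653403395
hair	brown_light_brown	rs1805006	A	-0.8301324746772354
hair	brown_light_brown	rs2228479	A	0.0702846635817877
hair	brown_light_brown	rs1110400	A	1.1870251014944595
hair	brown_light_brown	rs28777	A	-0.7391853175488764
hair	brown_light_brown	rs16891982	A	-0.44713821845370927
hair	brown_light_brown	rs12821256	A	0.4808511358927213
hair	brown_light_brown	rs4959270	A	0.30665054200567593
hair	brown_light_brown	rs12203592	A	0.1367494879924113
hair	brown_light_brown	rs1042602	A	-0.5817197956942671
hair	brown_light_brown	rs1800407	A	0.17432238732920227
hair	brown_light_brown	rs2402130	A	0.26109369742558847
hair	brown_light_brown	rs12913832	A	-1.1462284493493722
hair	brown_light_brown	rs2378249	A	-0.40576469852525027
hair	brown_light_brown	rs683	A	-1.5284735925692765
hair	blonde_dark_blonde	(intercept)		2.1596444346051396
hair	blonde_dark_blonde	rs11547464	A	-1.4679423516458647
hair	blonde_dark_blonde	rs885479	A	2.8450804364381517
hair	blonde_dark_blonde	rs1805008	A	-1.0539423500741014
hair	blonde_dark_blonde	rs1805005	A	0.17101969399260625
hair	blonde_dark_blonde	rs1805006	A	0.05284880250233062
hair	blonde_dark_blonde	rs2228479	A	-0.10085383887489158
hair	blonde_dark_blonde	rs1110400	A	-1.7177737396600885
hair	blonde_dark_blonde	rs28777	A	-0.567579044519025
hair	blonde_dark_blonde	rs16891982	A	-0.05710448327756272
hair	blonde_dark_blonde	rs12821256	A	0.17233413553334337
hair	blonde_dark_blonde	rs4959270	A	-1.1315601000451048
hair	blonde_dark_blonde	rs12203592	A	-0.29934972446070784
hair	blonde_dark_blonde	rs1042602	A	-0.6773939590374487
hair	blonde_dark_blonde	rs1800407	A	-0.5982257278247265
hair	blonde_dark_blonde	rs2402130	A	0.6330833981365556
hair	blonde_dark_blonde	rs12913832	A	-0.6243011079790439
hair	blonde_dark_blonde	rs2378249	A	0.0185605804720499
hair	blonde_dark_blonde	rs683	A	0.6660730510221973
hair	red	(intercept)		-2.9314625975023696
hair	red	rs11547464	A	-0.2558430994731596
hair	red	rs885479	A	0.1040030471983463
hair	red	rs1805008	A	2.9510213302453847
hair	red	rs1805005	A	-0.8623862215072001
hair	red	rs1805006	A	0.32767740861936756
hair	red	rs2228479	A	1.130894833668545
hair	red	rs1110400	A	-1.106728658459596
hair	red	rs28777	A	0.5393530298913992
hair	red	rs16891982	A	0.11546146194921071
hair	red	rs12821256	A	-0.38165857637924155
hair	red	rs4959270	A	1.7107336034185066
hair	red	rs12203592	A	0.5985673161933363
hair	red	rs1042602	A	-0.9373524451125604
hair	red	rs1800407	A	-0.018931589537307197
hair	red	rs2402130	A	0.3046808930491471
hair	red	rs12913832	A	-0.06438375842628347
hair	red	rs2378249	A	0.6127479639507027
hair	red	rs683	A	-0.007833848435859658
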