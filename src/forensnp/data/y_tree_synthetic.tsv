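node	marker_id	derived_allele	geography
YROOT			
Y-A	Y:A:1	1	Africa
Y-A	Y:A:2	1	Africa
Y-A1	Y:A1:1	1	Africa
Y-A1	Y:A1:2	1	Africa
Y-A2	Y:A2:1	1	Africa
Y-A2	Y:A2:2	1	Africa
Y-C	Y:C:1	1	Eastern Eurasia
Y-C	Y:C:2	1	Eastern Eurasia
Y-C1	Y:C1:1	1	Eastern Eurasia
Y-C1	Y:C1:2	1	Eastern Eurasia
Y-C2	Y:C2:1	1	Eastern Eurasia
Y-C2	Y:C2:2	1	Eastern Eurasia
Y-E	Y:E:1	1	Africa
Y-E	Y:E:2	1	Africa
Y-E1	Y:E1:1	1	Africa
Y-E1	Y:E1:2	1	Africa
Y-E1a	Y:E1a:1	1	Africa
Y-E1a	Y:E1a:2	1	Africa
Y-E2	Y:E2:1	1	Western Eurasia
Y-E2	Y:E2:2	1	Western Eurasia
Y-H	Y:H:1	1	South Asia
Y-H	Y:H:2	1	South Asia
Y-H1	Y:H1:1	1	South Asia
Y-H1	Y:H1:2	1	South Asia
Y-H2	Y:H2:1	1	South Asia
Y-H2	Y:H2:2	1	South Asia
Y-O	Y:O:1	1	Eastern Eurasia
Y-O	Y:O:2	1	Eastern Eurasia
Y-O1	Y:O1:1	1	Eastern Eurasia
Y-O1	Y:O1:2	1	Eastern Eurasia
Y-O1a	Y:O1a:1	1	Eastern Eurasia
Y-O1a	Y:O1a:2	1	Eastern Eurasia
Y-Q	Y:Q:1	1	Americas
Y-Q	Y:Q:2	1	Americas
Y-Q1	Y:Q1:1	1	Americas
Y-Q1	Y:Q1:2	1	Americas
Y-Q1a	Y:Q1a:1	1	Americas
Y-Q1a	Y:Q1a:2	1	Americas
Y-R	Y:R:1	1	Western Eurasia
Y-R	Y:R:2	1	Western Eurasia
Y-R1	Y:R1:1	1	Western Eurasia
Y-R1	Y:R1:2	1	Western Eurasia
Y-R1a	Y:R1a:1	1	Western Eurasia
Y-R1a	Y:R1a:2	1	Western Eurasia
Y-R2	Y:R2:1	1	South Asia
Y-R2	Y:R2:2	1	South Asia
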