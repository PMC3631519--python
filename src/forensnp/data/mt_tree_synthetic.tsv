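node	marker_id	derived_allele	geography
mtROOT			
mt-A	mt:A:1	1	Africa
mt-A	mt:A:2	1	Africa
mt-A1	mt:A1:1	1	Africa
mt-A1	mt:A1:2	1	Africa
mt-A2	mt:A2:1	1	Africa
mt-A2	mt:A2:2	1	Africa
mt-C	mt:C:1	1	Eastern Eurasia
mt-C	mt:C:2	1	Eastern Eurasia
mt-C1	mt:C1:1	1	Eastern Eurasia
mt-C1	mt:C1:2	1	Eastern Eurasia
mt-C2	mt:C2:1	1	Eastern Eurasia
mt-C2	mt:C2:2	1	Eastern Eurasia
mt-E	mt:E:1	1	Africa
mt-E	mt:E:2	1	Africa
mt-E1	mt:E1:1	1	Africa
mt-E1	mt:E1:2	1	Africa
mt-E1a	mt:E1a:1	1	Africa
mt-E1a	mt:E1a:2	1	Africa
mt-E2	mt:E2:1	1	Western Eurasia
mt-E2	mt:E2:2	1	Western Eurasia
mt-H	mt:H:1	1	South Asia
mt-H	mt:H:2	1	South Asia
mt-H1	mt:H1:1	1	South Asia
mt-H1	mt:H1:2	1	South Asia
mt-H2	mt:H2:1	1	South Asia
mt-H2	mt:H2:2	1	South Asia
mt-O	mt:O:1	1	Eastern Eurasia
mt-O	mt:O:2	1	Eastern Eurasia
mt-O1	mt:O1:1	1	Eastern Eurasia
mt-O1	mt:O1:2	1	Eastern Eurasia
mt-O1a	mt:O1a:1	1	Eastern Eurasia
mt-O1a	mt:O1a:2	1	Eastern Eurasia
mt-Q	mt:Q:1	1	Americas
mt-Q	mt:Q:2	1	Americas
mt-Q1	mt:Q1:1	1	Americas
mt-Q1	mt:Q1:2	1	Americas
mt-Q1a	mt:Q1a:1	1	Americas
mt-Q1a	mt:Q1a:2	1	Americas
mt-R	mt:R:1	1	Western Eurasia
mt-R	mt:R:2	1	Western Eurasia
mt-R1	mt:R1:1	1	Western Eurasia
mt-R1	mt:R1:2	1	Western Eurasia
mt-R1a	mt:R1a:1	1	Western Eurasia
mt-R1a	mt:R1a:2	1	Western Eurasia
mt-R2	mt:R2:1	1	South Asia
mt-R2	mt:R2:2	1	South Asia
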