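trait	category	term	effect_allele	beta
eye	intermediate	(intercept)		-0.48000365465976436
eye	intermediate	rs12913832	A	3.1166190755196754
eye	intermediate	rs1800407	A	-0.320341661466099
eye	intermediate	rs12896399	A	-0.7107615725664748
eye	intermediate	rs16891982	A	-0.3770213694213598
eye	intermediate	rs1393350	A	-0.8373950310523779
eye	intermediate	rs12203592	A	-0.030968267552258788
eye	brown	(intercept)		-1.4911967771943873
eye	brown	rs12913832	A	-0.1511211799105242
eye	brown	rs1800407	A	2.795967888819125
eye	brown	rs12896399	A	0.3167655487897254
eye	brown	rs16891982	A	0.36121565674557626
eye	brown	rs1393350	A	0.11249005798645312
eye	brown	rs12203592	A	-0.694394733423417
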