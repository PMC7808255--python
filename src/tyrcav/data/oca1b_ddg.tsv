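mutation	ddg	unfolding_published	predicted_effect_published	ddv_published
W39R	1.2	0.88	Severe	1248
R77G	5.7	1	Severe	1670
K142M	-1.7	0.06	Severe	928
S323R	0.8	0.8	Moderate	255
T325A	-0.3	0.39	Severe	540
M370V	4.5	1	Severe	579
V393D	4.8	1	Severe	1656
R402G	2.1	0.97	Severe	685
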