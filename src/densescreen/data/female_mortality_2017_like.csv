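# Age-specific all-cause mortality for US women, annual probability of death qx.
# Emulates the US Life Tables 2017 (NVSS, women of all ethnicities): transcribed
# approximation to three significant figures. Not a verbatim copy of the NVSS
# release.
age,annual_probability
55,0.00424
56,0.00462
57,0.00504
58,0.00550
59,0.00598
60,0.00648
61,0.00700
62,0.00753
63,0.00808
64,0.00868
65,0.00936
66,0.01016
67,0.01106
68,0.01205
69,0.01316
70,0.01446
71,0.01591
72,0.01752
73,0.01930
74,0.02130
75,0.02354
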