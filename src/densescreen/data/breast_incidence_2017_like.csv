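# Age-specific female breast cancer incidence, annual probability per woman.
# Emulates SEER age-adjusted incidence rates 2017 (all races, female breast):
# transcribed approximation, piecewise-linear through the 5-year age-group
# rates per 100,000 (midpoints 52:220.5, 57:264.1, 62:345.4, 67:421.3,
# 72:461.3, 77:465.8). Not a verbatim copy of the SEER release.
age,annual_probability
55,0.002467
56,0.002554
57,0.002641
58,0.002804
59,0.002966
60,0.003129
61,0.003291
62,0.003454
63,0.003606
64,0.003758
65,0.003909
66,0.004061
67,0.004213
68,0.004293
69,0.004373
70,0.004453
71,0.004533
72,0.004613
73,0.004622
74,0.004631
75,0.004640
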