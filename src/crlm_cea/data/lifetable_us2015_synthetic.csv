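# Synthetic all-population period life table, ages 65-100.
# Gompertz fit q(age) = exp(-10.491 + 0.0947*age), constructed once to
# emulate the magnitude and age-gradient of the published 2015 US period
# life table (no network access at build time); values are synthetic.
age,qx
65,0.013095
66,0.014396
67,0.015826
68,0.017398
69,0.019126
70,0.021026
71,0.023114
72,0.025410
73,0.027934
74,0.030709
75,0.033759
76,0.037113
77,0.040799
78,0.044851
79,0.049306
80,0.054204
81,0.059588
82,0.065507
83,0.072014
84,0.079167
85,0.087030
86,0.095675
87,0.105178
88,0.115625
89,0.127110
90,0.139736
91,0.153616
92,0.168874
93,0.185649
94,0.204089
95,0.224361
96,0.246646
97,0.271145
98,0.298078
99,0.327686
100,0.360235
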