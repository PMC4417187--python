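# name: yeast
# status: reconstructed
# description: Relative DR-mediated deletion propensity vs repeat length,
#   reconstructed as a monotone log-linear calibration with a gentler slope
#   than the phage calibration, in the spirit of deletion assays on yeast
#   mtDNA. Replace this file to use a different calibration.
# min_len: 10
# log10_slope: 0.1760913
# log10_intercept: -1.760913
length	weight
10	1
11	1.5
12	2.25
13	3.375
14	5.0625
15	7.59375
16	11.390625
17	17.0859375
18	25.62890625
19	38.443359375
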