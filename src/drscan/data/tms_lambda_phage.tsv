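# name: lambda_phage
# status: reconstructed
# description: Relative DR-mediated deletion propensity vs repeat length,
#   reconstructed as a monotone log-linear calibration in the spirit of
#   deletion-frequency assays on engineered phage lambda DNA (frequency
#   roughly doubling per additional base pair of repeat). Replace this file
#   to use a different calibration; weights are relative, so only ratios
#   between lengths matter for comparisons.
# min_len: 10
# log10_slope: 0.30103
# log10_intercept: -3.0103
length	weight
10	1
11	2
12	4
13	8
14	16
15	32
16	64
17	128
18	256
19	512
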