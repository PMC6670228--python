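construct	regenerated	expressing	low_copy	plants_tested	grains_tested	plants_clear	grains_clear	plants_any	grains_any
alpha1_sgRNA	40	38	21	38	325	3	4	3	8
alpha2_sgRNA	32	12	4	12	288	7	13	7	19
gamma3_sgRNA	36	35	26	35	280	10	10	15	23
alpha2gamma3_sgRNA	42	32	12	32	256	3	11	11	20
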