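tissue,wavelength_nm,mu_a_per_m,mu_s_prime_per_m
scalp_skull,630,19,858
scalp_skull,700,13,900
scalp_skull,810,16,760
csf,630,4,250
csf,700,4,250
csf,810,2.6,250
gray_matter,630,127.25,990
gray_matter,700,62.91,880
gray_matter,810,57.09,746
white_matter,630,66.11,4400
white_matter,700,32.52,4356
white_matter,810,20.77,4070
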