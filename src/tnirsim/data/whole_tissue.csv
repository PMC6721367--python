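tissue,wavelength_nm,mu_a_per_m
gray_matter,630,127.25
gray_matter,700,62.91
gray_matter,810,57.09
white_matter,630,66.11
white_matter,700,32.52
white_matter,810,20.77
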