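tissue,wavelength_nm,chromophore,mu_a_per_m
gray_matter,630,water,0.26
gray_matter,700,water,0.5
gray_matter,810,water,1.66
gray_matter,630,fat,0.04
gray_matter,700,fat,0.03
gray_matter,810,fat,0.05
gray_matter,630,oxyhemoglobin,14.06
gray_matter,700,oxyhemoglobin,12.17
gray_matter,810,oxyhemoglobin,22.44
gray_matter,630,deoxyhemoglobin,73
gray_matter,700,deoxyhemoglobin,34.2
gray_matter,810,deoxyhemoglobin,15.48
gray_matter,630,oxidized_cco,35.64
gray_matter,700,oxidized_cco,14.04
gray_matter,810,oxidized_cco,16.2
gray_matter,630,reduced_cco,4.25
gray_matter,700,reduced_cco,1.97
gray_matter,810,reduced_cco,1.26
white_matter,630,water,0.23
white_matter,700,water,0.43
white_matter,810,water,1.45
white_matter,630,fat,0.08
white_matter,700,fat,0.06
white_matter,810,fat,0.1
white_matter,630,oxyhemoglobin,3.37
white_matter,700,oxyhemoglobin,2.92
white_matter,810,oxyhemoglobin,5.38
white_matter,630,deoxyhemoglobin,59.92
white_matter,700,deoxyhemoglobin,28.11
white_matter,810,deoxyhemoglobin,12.72
white_matter,630,oxidized_cco,2.34
white_matter,700,oxidized_cco,0.9
white_matter,810,oxidized_cco,1.1
white_matter,630,reduced_cco,0.13
white_matter,700,reduced_cco,0.06
white_matter,810,reduced_cco,0.04
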