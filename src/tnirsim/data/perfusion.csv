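tissue,blood_specific_heat_j_per_kg_k,blood_perfusion_per_s,blood_density_kg_per_m3,metabolic_heat_w_per_m3
scalp,3600,0.00143,1050,363
skull,3600,0.000143,1050,70
csf,3600,0,1050,0
brain,3600,0.08,1050,10437
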