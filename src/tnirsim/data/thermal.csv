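tissue,thermal_conductivity_w_per_m_c,density_kg_per_m3,metabolic_heat_w_per_m3
scalp,0.342,1100,363
skull,1.15,1990,70
csf,0.61,0,0
brain,0.57,0.08,10437
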