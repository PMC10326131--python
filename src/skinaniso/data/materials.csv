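name,density_kg_m3,young_modulus_pa,mean_rrt
Techsil 25 Silicone,928,463260,503
Polyurethane,1237,2517780,323
MVQ Elastomer,1348,330000,820
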