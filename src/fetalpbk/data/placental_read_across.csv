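compound,molecular_weight_g_per_mol,logkow,ratio_low,ratio_high
Atazanavir,705,4.08,0.14,
Buprenorphine,468,3.93,0.14,0.35
Lopinavir,629,3.91,0.22,
Nicardipine,480,3.82,0.01,
Nelfinavir,568,4.61,0.02,
Ritonavir,721,4.30,0.45,
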