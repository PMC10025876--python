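species,stage,body_weight_kg,liver_mass_g
rat,,0.25,8.6
human,,70.0,1800
human,gw20,74.0,1800
human,gw40,82.0,1800
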