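organ,stage,f_lipid,f_water
plasma,,0.006,0.94
brain,,0.11,0.77
liver,,0.07,0.72
fat,,0.85,0.12
muscle,,0.03,0.76
kidney,,0.05,0.78
gut_tissue,,0.05,0.75
rest_of_body,,0.04,0.75
placenta,,0.02,0.85
fetal_tissue,gw20,0.004,0.92
fetal_tissue,gw40,0.12,0.82
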