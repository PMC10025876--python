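# Deltamethrin (DLT) compound definition. All numeric fields carry explicit units
# in their key names. Partition coefficients for brain/fat/liver/muscle are the
# rat-fitted values; permeabilities are package defaults for the packaged
# reference surface areas (see docs/methods.md).
name: deltamethrin
molecular_weight_g_per_mol: 505.2
logkow_measured: 6.4
lipophilicity_correction: 3.6
fraction_unbound_plasma: 0.10
solubility_mg_per_l: 323.2
papp_ab_cm_per_s: 4.34e-6
papp_ba_cm_per_s: 1.76e-6
fraction_absorbed_cap: 0.75
partition_coefficients:        # tissue:plasma, dimensionless
  brain: 0.2
  fat: 172.8
  liver: 8.0
  muscle: 4.25
permeabilities_cm_per_min:
  brain: 10.0
  fat: 0.1
  liver: 1.0
  muscle: 0.1
  gut_tissue: 1.0
  kidney: 1.0
  rest_of_body: 1.0
  placenta: 1.0
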