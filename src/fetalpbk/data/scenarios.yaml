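# The seven pregnant-human case studies. "DD" = data-driven. Cases with a fixed
# maternal brain partition coefficient (brain_pc) use the rat-fitted value 0.17;
# cases with brain_ratio_target calibrate the brain PC so the achieved steady-state
# maternal brain/plasma Cmax ratio hits the target. fetal_maternal_target is the
# fetal/maternal plasma Cmax ratio the placental-barrier calibration must achieve
# (0.2 = read-across median, 1 = fully impaired barrier, 1.2 = worst-case
# accumulation). Solubility in mg/l (2.7e-3 = in water, 323 = glycerol formal).
- {case_id: case1, label: "DD + low sol.", brain_pc: 0.17, fetal_maternal_target: 0.2, solubility_mg_per_l: 2.7e-3, gestational_age: 20}
- {case_id: case2, label: "DD", brain_pc: 0.17, fetal_maternal_target: 0.2, solubility_mg_per_l: 323.0, gestational_age: 20}
- {case_id: case3, label: "DD + no BBB", brain_ratio_target: 1.0, fetal_maternal_target: 0.2, solubility_mg_per_l: 323.0, gestational_age: 20}
- {case_id: case4, label: "DD + no BPB", brain_pc: 0.17, fetal_maternal_target: 1.0, solubility_mg_per_l: 323.0, gestational_age: 20}
- {case_id: case5, label: "DD + no BBB + no BPB", brain_ratio_target: 1.0, fetal_maternal_target: 1.0, solubility_mg_per_l: 323.0, gestational_age: 20}
- {case_id: case6, label: "Worst", brain_ratio_target: 1.5, fetal_maternal_target: 1.2, solubility_mg_per_l: 323.0, gestational_age: 20}
- {case_id: case7, label: "Worst + 40 weeks", brain_ratio_target: 1.5, fetal_maternal_target: 1.2, solubility_mg_per_l: 323.0, gestational_age: 40}
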