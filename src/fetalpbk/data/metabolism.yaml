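# Michaelis-Menten metabolism parameters for deltamethrin. Rat clears via CES1
# (cytosolic, microsomal, plasma) and CYP1A2; in humans CES1 covers ~97% of
# clearance, so only tissue CES1 (cytosol + microsome, no plasma) is modeled.
# correction_factor scales Vmax (in-vitro to in-vivo translation).
rat:
  - {enzyme: CES1, location: cytosol, compartment: liver, km_uM: 0.93, vmax_uM_per_min: 0.12, correction_factor: 4.3}
  - {enzyme: CES1, location: microsome, compartment: liver, km_uM: 0.76, vmax_uM_per_min: 0.10, correction_factor: 4.3}
  - {enzyme: CES1, location: plasma, compartment: plasma, km_uM: 1.79, vmax_uM_per_min: 0.66, correction_factor: 4.3}
  - {enzyme: CYP1A2, location: microsome, compartment: liver, km_uM: 0.76, vmax_uM_per_min: 1.09, correction_factor: 4.3}
human:
  - {enzyme: CES1, location: cytosol, compartment: liver, km_uM: 1.18, vmax_uM_per_min: 138.13, correction_factor: 1.0}
  - {enzyme: CES1, location: microsome, compartment: liver, km_uM: 3.81, vmax_uM_per_min: 364.60, correction_factor: 1.0}
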