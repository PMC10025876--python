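# Fittable parameter template: rat-model optima with lower/upper fitting bounds.
# "optimal" is the published rat fit; permeability optima are PK-Sim-normalized
# and serve as template values only (package defaults differ; see methods note).
- {path: lipophilicity_correction, optimal: 3.6, lower: 1.0, upper: 4.3, unit: "a.u."}
- {path: solubility, optimal: 323.2, lower: 0.01, upper: 1000.0, unit: "mg/l"}
- {path: metabolism_correction, optimal: 4.3, lower: 1.0, upper: 10.0, unit: "a.u."}
- {path: partition_coefficients.brain, optimal: 0.2, lower: 0.01, upper: 10.0, unit: "a.u."}
- {path: partition_coefficients.fat, optimal: 172.8, lower: 1.0, upper: 1000.0, unit: "a.u."}
- {path: partition_coefficients.liver, optimal: 8.0, lower: 0.1, upper: 100.0, unit: "a.u."}
- {path: partition_coefficients.muscle, optimal: 4.25, lower: 0.1, upper: 100.0, unit: "a.u."}
- {path: permeabilities.brain, optimal: 10.0, lower: 1.0e-7, upper: 10.0, unit: "cm/min"}
- {path: permeabilities.fat, optimal: 2.5e-5, lower: 1.0e-7, upper: 10.0, unit: "cm/min"}
- {path: permeabilities.liver, optimal: 2.8e-6, lower: 1.0e-7, upper: 10.0, unit: "cm/min"}
- {path: permeabilities.muscle, optimal: 2.5e-5, lower: 1.0e-7, upper: 10.0, unit: "cm/min"}
- {path: weibull_shape, optimal: 0.01, lower: 1.0e-3, upper: 5.0, unit: "a.u."}
- {path: weibull_time50, optimal: 1000.0, lower: 1.0e-3, upper: 1000.0, unit: "min"}
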