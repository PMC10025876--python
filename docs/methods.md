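# Methods

## Scope and intent

`fetalpbk` estimates how much deltamethrin (DLT), a lipophilic pyrethroid
insecticide, can reach the human fetal brain when the mother is exposed
orally at the acceptable daily intake (ADI, 0.01 mg/kg/day), and compares
that exposure with the lowest benchmark concentration of the in vitro
developmental-neurotoxicity testing battery (0.5 µM, rat neuronal-network
formation; the 0.6 µM human neural-progenitor endpoint is selectable).  The
pipeline is: (1) a whole-body rat kinetic model whose compound-specific
parameters are estimated from tissue toxicokinetic data; (2) translation to
an adult and then a pregnant human model; (3) scenario-based calibration of
the blood-brain and blood-placenta barriers to target concentration ratios;
(4) fetal-brain exposure estimation and margins of safety.

The package deliberately does **not** try to reproduce any proprietary
physiology database.  Absolute tissue concentrations therefore depend on the
packaged reference anatomy; the portable outputs are ratio- and
calibration-based quantities (achieved barrier ratios, fold errors, margin
arithmetic), and the acceptance checks are built around those.

## Model structure

Arterial and venous blood pools connect permeability-limited organs (gut
tissue, liver, brain, fat, muscle, kidney, rest of body; plus placenta when
pregnant).  Every organ consists of a vascular sub-compartment in series with
the circulation and a tissue sub-compartment behind a permeability barrier:

    dA_vas/dt = Q (C_art − C_vas) − PS·fup (C_vas − C_tis/K)
    dA_tis/dt = PS·fup (C_vas − C_tis/K) − metabolism

with `PS = permeability (cm/min) × exchange area (dm²) × 0.1` in L/min.  The
unbound plasma fraction `fup` (0.10 for DLT, the measured value) scales the
exchange *rate*; the equilibrium tissue:plasma ratio equals the partition
coefficient `K` defined on total concentrations.  Consequently the achieved
Cmax tissue/plasma ratio is always bounded by `K`, which the test suite
asserts for every organ.  Gut venous outflow perfuses the liver (portal
vein); venous return equals cardiac output by construction in every
physiology, sampled or not.  Five percent of each organ volume is treated as
its vascular space.

**Absorption.**  Oral doses enter a gut-lumen pool.  Only the
gastrointestinal-availability cap (75% for DLT) of each dose enters the
dissolvable pool; the remainder is ledgered as unabsorbed at dose time —
this implements the absorption cap exactly while keeping the ODE smooth.
Dissolution follows a Weibull profile `F(t) = 1 − exp(−ln2 (t/t50)^shape)`
(`t50` = 50%-dissolution time, 1000 min; shape 0.01), implemented as a
hazard on the undissolved pool.  Shapes below one concentrate a finite
dissolved fraction at `t → 0`; that fraction (evaluated at the 0.01-min
hazard-clock floor) is transferred analytically at each dose event, so the
single-dose profile is exact.  Under repeated dosing the clock resets each
dose and carry-over material re-experiences the early hazard; at the doses
studied the carry-over pool is small and this approximation is immaterial.
Dissolution stops when the lumen concentration reaches the formulation
solubility (323 mg/L in glycerol formal; 2.7·10⁻³ mg/L in water).  Dissolved
drug is absorbed into the portal blood with a first-order rate derived from
the Caco-2 apical→basolateral permeability (4.34·10⁻⁶ cm/s) and the gut
exchange area, so absorbed material passes the liver before reaching the
systemic circulation.

**Metabolism.**  Saturable (Michaelis–Menten) clearance on the unbound local
concentration; intracellular unbound fraction is taken as one, plasma uses
`fup`.  Rat: CES1 in liver cytosol, liver microsomes and plasma, plus
hepatic CYP1A2 (Km 0.76–1.79 µM, Vmax 0.10–1.09 µM/min); a fitted
correction factor (4.3, bounds 1–10) multiplies every Vmax — the minimal
interpretation that rescales clearance; a configurable alternative would
also divide Km.  Human: CES1 cytosol + microsomes only (Km 1.18/3.81 µM,
Vmax 138/365 µM/min), since CES1 covers ~97% of human DLT clearance; no
plasma esterase, no CYP.  Both human pathways are placed in the liver tissue
compartment.  An optional helper rescales human Vmax so the apparent
intrinsic clearance equals the reported 646 ml/min/g liver.  Elimination is
exclusively metabolic; no renal clearance or transporters are modeled.

**Maternal–fetal circuit.**  The placenta is maternally perfused and
exchanges with a fetal plasma compartment across the blood-placenta barrier,
`J = PS_bpb · fup (C_placenta/K_placenta − C_fetal/r)`, where `PS_bpb` is
the calibration handle and `r` a fetal-side retention factor (default 1).
Fetal plasma exchanges with a single lumped fetal tissue compartment; the
model resolves no fetal organs, which is why fetal brain exposure is
estimated by the ratio identity

    C_brain,fet,max = C_plasma,fet,max × C_brain,mat,max / C_plasma,mat,max

assuming the maternal brain/plasma ratio carries over to the fetus.  The
fetus does not grow during a simulation; gestational week 20 or 40 selects a
fixed anatomy.

## Partitioning and the lipophilicity correction

Measured logKow for DLT is 6.4, far outside the domain of composition-based
partitioning rules, and measured plasma binding (fup 10%) contradicts
binding predicted from that lipophilicity.  The model therefore uses an
effective lipophilicity = measured logKow / fitted correction factor
(6.4/3.6 = 1.78 ≈ the fitted effective value 1.8; division is the one
algebraic form that reproduces both fitted numbers simultaneously).  Brain
(0.2), fat (172.8), liver (8.0) and muscle (4.25) use directly fitted
tissue:plasma coefficients.  All other organs use a lipid/water rule in
which tissue equilibrates with the unbound plasma fraction:

    K = fup (f_lipid · 10^logKow_eff + f_water) / f_water,plasma

This is monotone in effective lipophilicity, reduces to a water/plasma-water
term for lipid-free tissue, and gives the low lumped-fetal-tissue partition
(≈0.12 at week 20) that makes the simulated fetal tissue Cmax fall below the
ratio-based fetal brain estimate — the conservative ordering the scenario
suite asserts.

## Reference physiology

Organ volumes, blood flows and exchange areas for the 0.25-kg rat, the 70-kg
adult human, and the pregnant human at gestational weeks 20 and 40
(reference body weights 74 and 82 kg) are compiled from standard literature
reference tables into versioned CSVs.  Maternal organs scale linearly with
body weight; placental and fetal compartments are set by gestational age
alone and grow monotonically between weeks 20 and 40.  Permeabilities for
brain/fat/liver/muscle are package defaults chosen so that, with these
exchange areas, tissue uptake time-scales are physiological: the brain is
effectively flow-limited, and adipose uptake has a ~2-week human time-scale,
which is what makes ~60 days of daily dosing necessary to reach steady state
(final-week trough drift < 1%/day, asserted).  The published permeability
estimates from the original rat fit are normalized to a different internal
geometry and are retained only as template values and fitting bounds;
absolute permeability values are explicitly not portable between the two
geometries.

Population variability: mean-preserving lognormal scatter
(`exp(N(−σ²/2, σ²))`, `σ² = ln(1+CV²)`) with a default CV of 0.2 on organ
volumes, flows and metabolic capacity (no published CVs exist; 0.2 is a
conventional inter-individual figure).  Cardiac output is recomputed as the
sum of sampled flows, so flow conservation survives sampling.

## Parameter estimation

All dose/route arms (1, 2, 10 mg/kg oral; 0.5 mg/kg IV) and tissues (plasma,
brain, liver, fat, muscle) are fitted simultaneously by bounded least
squares on log residuals `log(pred+ε) − log(obs+ε)` (ε = 10⁻⁶ µM floor for
below-quantification points); log residuals weight a 20-fold dose range and
orders-of-magnitude tissue differences evenly, and make the objective
invariant to the concentration unit.  Optimization runs in log10 parameter
space (trust-region reflective) from 8 seeded Latin-hypercube starts,
screened by initial objective with the best two polished.  The default
fittable set is the identifiable core under this design — the four fitted
partition coefficients and the metabolism correction factor; solubility is
not rate-limiting at the fitted doses in the high-availability vehicle and
the lipophilicity correction only reaches organs without fitted
coefficients, so both are held at their packaged values by default (the full
14-row template with bounds ships with the package and any subset can be
fitted).  Model adequacy is judged by the field's 2-fold criterion on Cmax
(predicted/observed per dose–tissue arm).

## Synthetic data

The generator emulates the *structure* of the rat studies behind the
original fit (doses, routes, tissues, 0.5–96 h log-spaced sampling plus a
14-day adipose tail point, LLOQ 10⁻⁵ µM) with the packaged parameter values
as ground truth and mean-preserving multiplicative lognormal noise (default
CV 20%).  A reduced-absorption variant (scaled Caco-2 permeability and
absorption cap) emulates a poorly absorbed vehicle; evaluating the
standard-vehicle model on it reproduces the expected systematic
over-prediction.  What passing tests show: the estimation machinery is
unbiased and closes the loop on data *generated by the model itself*; they
cannot show that the model family is correct for real rat data, nor do the
synthetic datasets carry real-data features such as inter-animal
variability, assay-specific error structure, or sparse/irregular sampling.

## Barrier calibration and scenarios

Human brain and cord-blood data for DLT do not exist, so the two barriers
are calibrated to scenario targets on the median individual:

* brain: the brain partition coefficient is adjusted until the steady-state
  (last dosing interval) maternal brain/plasma Cmax ratio equals the target
  (1 impaired, 1.5 worst case); since the brain is flow-limited, the ratio
  tracks the coefficient and a proportional update converges in 2–3
  simulations (0.5% internal tolerance against the 1% acceptance band).
* placenta: `PS_bpb` is adjusted by bracketed regula falsi on log-log
  coordinates until the fetal/maternal plasma Cmax ratio equals the target
  (0.2, the read-across median over six high-molecular-weight lipophilic
  analogues, ranges collapsed at their midpoint).  Symmetric passive
  diffusion saturates at a ratio of ~1 (kinetic lag keeps it slightly
  below), so targets ≥ 1 (impaired barrier, worst-case 1.2) are realized at
  fast exchange through the fetal retention factor instead.

The packaged seven-case grid combines: the rat-derived fixed brain
coefficient (0.17) vs. calibrated ratios 1 and 1.5; placental targets 0.2,
1 and 1.2; water vs. glycerol-formal solubility; weeks 20 and 40.  Case
runs calibrate once on the median individual, then sample the population
(default 100 individuals, 60 days — the study conditions; tests use smaller
populations and shorter horizons where only structure is being checked) and
report per-individual steady-state maxima, the ratio-based fetal-brain
estimate, both margins of safety, and population mean ± SD trajectories.
The margin of safety is benchmark/Cmax; the dose at which the margin reaches
one is obtained by dose-proportional extrapolation (ADI × MoS), valid
because concentrations at the ADI are in the nM range, far below the µM-scale
Km values (dose-doubling changes concentration ratios by < 0.1%, asserted).

Within the realized model the achieved maternal brain/plasma ratio for the
fixed-coefficient cases equals the coefficient (~0.17), not the lower
kinetically limited value reported from the original software's internal
permeability normalization; this is a known, documented consequence of not
reproducing that geometry, and it is conservative (higher estimated brain
exposure).

## Numerical choices

* Stiff BDF integration with an analytic Jacobian (constant linear part
  assembled once; Michaelis–Menten and dissolution contributions added per
  evaluation).  Defaults rtol 10⁻⁸ / atol 10⁻¹² µmol; scenario and
  calibration runs use rtol 10⁻⁶ / atol 10⁻¹⁰.
* The mass ledger (dosed = in-system + metabolized + unabsorbed) is exact in
  the continuous system; the numerical residual is asserted below 10⁻⁶
  relative (observed ~10⁻¹⁵).
* Output grids carry ≥ 20 points per dosing interval; scenario runs use 288
  (5-minute spacing) because the daily absorption peak that sets the plasma
  Cmax is ~30 min wide and dense output is cheap relative to solver steps.
* Integration restarts at every dose event (states are discontinuous there).
* Reported concentrations are clipped at zero (solver noise floor); ledger
  arrays are raw.
* Linear-regime verification: with metabolism off the system is linear and
  the integrator is checked against the closed-form matrix-exponential
  solution to within 10× rtol.

## Limitations

* Lipoprotein binding and its maternal/fetal differences are not modeled;
  margins refer to total concentrations (unbound margins would be larger).
* No metabolite kinetics, enterohepatic recirculation, renal clearance,
  transporters, inhalation/dermal routes, or neonatal physiology.
* The fetal compartment is a single lumped tissue; the brain estimate rests
  entirely on the maternal ratio-transfer assumption.
* Absolute concentrations inherit the packaged reference anatomy; only
  ratio/calibration outputs should be compared across implementations.
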