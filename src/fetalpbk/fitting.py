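"""Bounded least-squares estimation of kinetic parameters from tissue TK data.

All dose/route arms and tissues are fitted *simultaneously*: the objective is
the sum of squared log-scale residuals

    sum over observations of (log(pred + eps) - log(obs + eps))^2

Log residuals are used because the data span a >20-fold dose range and
tissue concentrations differ by orders of magnitude; the epsilon floor
(1e-6 µM) keeps below-detection points finite.  Optimization runs in log10
parameter space under box bounds (trust-region reflective), seeded with a
Latin-hypercube multi-start: starts are screened by their initial objective
and the best few refined.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import least_squares
from scipy.stats import qmc

from .compound import CompoundSpec, FittableParameter, mass_to_molar
from .errors import FitError
from .pbk_core import DosingRegimen, MetabolismSpec, build_model, simulate
from .physiology import PhysiologySet

EPS_FLOOR_UM = 1e-6

#: parameter paths identifiable from the standard study design; the default
#: fittable set (remaining template rows are held at their packaged values)
DEFAULT_FIT_PATHS = (
    "partition_coefficients.brain",
    "partition_coefficients.fat",
    "partition_coefficients.liver",
    "partition_coefficients.muscle",
    "metabolism_correction",
)


class TKObservation(BaseModel):
    """One measured tissue concentration (µM) at one time after one dose."""

    time: float = Field(ge=0.0, description="min after first dose")
    dose: float = Field(ge=0.0, description="mg/kg")
    route: Literal["oral", "iv"]
    tissue: str
    concentration: float = Field(ge=0.0, description="µM")
    study_label: str = ""


@dataclass
class FitTemplate:
    """Everything needed to rebuild the model during fitting."""

    phys: PhysiologySet
    compound: CompoundSpec
    metabolism: list[MetabolismSpec]
    base_regimen: DosingRegimen
    rtol: float = 1e-7
    atol: float = 1e-11
    points_per_interval: int = 120


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective_value: float
    converged: bool
    at_bound_flags: dict[str, bool]
    fold_errors: dict[tuple, float] = field(default_factory=dict)
    n_objective_evals: int = 0

    @property
    def max_fold_error(self) -> float:
        return max_fold_error(self.fold_errors)


def max_fold_error(fold_errors: dict) -> float:
    """Worst-case fold deviation: max of (ratio, 1/ratio) over all arms."""
    if not fold_errors:
        return float("nan")
    return max(max(f, 1.0 / f) for f in fold_errors.values())


def apply_parameters(
    compound: CompoundSpec,
    regimen: DosingRegimen,
    metabolism: list[MetabolismSpec],
    values: dict[str, float],
) -> tuple[CompoundSpec, DosingRegimen, list[MetabolismSpec]]:
    """Return copies of the inputs with the named parameter paths replaced."""
    comp_update: dict = {}
    pcs = dict(compound.partition_coefficients)
    perms = dict(compound.permeabilities)
    reg_update: dict = {}
    met = list(metabolism)
    for path, value in values.items():
        head, _, tail = path.partition(".")
        if head == "partition_coefficients":
            pcs[tail] = value
        elif head == "permeabilities":
            perms[tail] = value
        elif path in ("lipophilicity_correction", "solubility", "fraction_unbound_plasma", "papp_ab"):
            comp_update[path] = value
        elif path == "metabolism_correction":
            met = [m.model_copy(update={"correction_factor": value}) for m in met]
        elif path == "weibull_shape":
            reg_update["weibull_shape"] = value
        elif path == "weibull_time50":
            reg_update["weibull_time50"] = value
        else:
            raise KeyError(f"unknown fittable parameter path: {path!r}")
    comp_update["partition_coefficients"] = pcs
    comp_update["permeabilities"] = perms
    new_compound = compound.model_copy(update=comp_update)
    new_regimen = regimen.model_copy(update=reg_update) if reg_update else regimen
    return new_compound, new_regimen, met


def log_residuals(pred, obs, eps: float = EPS_FLOOR_UM) -> np.ndarray:
    """Log-scale residuals log(pred+eps) - log(obs+eps).

    Invariant (up to the epsilon floor) under a global rescaling of all
    concentrations, so the objective does not depend on the concentration unit.
    """
    return np.log(np.asarray(pred) + eps) - np.log(np.asarray(obs) + eps)


def _arms(data: Sequence[TKObservation]) -> dict[tuple, list[TKObservation]]:
    arms: dict[tuple, list[TKObservation]] = {}
    for obs in data:
        arms.setdefault((obs.route, obs.dose), []).append(obs)
    return arms


def _simulate_arms(
    template: FitTemplate, values: dict[str, float], arms: dict[tuple, list[TKObservation]]
):
    compound, regimen, metabolism = apply_parameters(
        template.compound, template.base_regimen, template.metabolism, values
    )
    results = {}
    for (route, dose), obs_list in arms.items():
        reg = regimen.model_copy(update={"route": route, "dose": dose})
        model = build_model(template.phys, compound, metabolism, reg)
        t_max = max(o.time for o in obs_list)
        duration = max(t_max * 1.02, reg.interval_min * reg.n_doses) / 1440.0
        obs_times = np.array(sorted({o.time for o in obs_list}))
        # union an early log-spaced grid so single-dose peaks are resolved
        early = np.geomspace(1.0, duration * 1440.0, 80)
        results[(route, dose)] = simulate(
            model,
            duration,
            rtol=template.rtol,
            atol=template.atol,
            points_per_interval=template.points_per_interval,
            extra_times=np.concatenate([obs_times, early]),
        )
    return results


def _residuals(template, arms, paths, x_linear) -> np.ndarray:
    values = dict(zip(paths, x_linear))
    sims = _simulate_arms(template, values, arms)
    res = []
    for key, obs_list in arms.items():
        sim = sims[key]
        for obs in obs_list:
            pred = float(np.interp(obs.time, sim.time, sim.concentrations[obs.tissue]))
            res.append(float(log_residuals(pred, obs.concentration)))
    return np.asarray(res)


def fit_parameters(
    template: FitTemplate,
    data: Sequence[TKObservation],
    params: Sequence[FittableParameter],
    seed: int = 0,
    n_starts: int = 8,
    n_refine: int = 2,
    max_nfev: int = 60,
    include_template_start: bool = True,
) -> FitResult:
    """Simultaneous bounded least-squares fit over all dose/route arms.

    Deterministic for a fixed seed.  ``n_starts`` Latin-hypercube starts (in
    log10 parameter space) are screened by their initial objective; the best
    ``n_refine`` are polished with trust-region reflective least squares.
    """
    data = list(data)
    if not data:
        raise FitError("no observations supplied")
    arms = _arms(data)
    fitted_tissues = {o.tissue for o in data}
    paths = [p.path for p in params]
    lb = np.log10([p.lower_bound for p in params])
    ub = np.log10([p.upper_bound for p in params])
    x_opt = np.log10([p.optimal for p in params])

    evals = 0

    def fun(x_log):
        nonlocal evals
        evals += 1
        return _residuals(template, arms, paths, 10.0 ** np.asarray(x_log))

    sampler = qmc.LatinHypercube(d=len(params), seed=seed)
    starts = lb + sampler.random(n_starts) * (ub - lb)
    if include_template_start:
        starts = np.vstack([x_opt, starts[: max(n_starts - 1, 0)]])

    scored = []
    for x0 in starts:
        try:
            r = fun(x0)
            ssq = float(r @ r)
        except Exception:
            ssq = np.inf
        if np.isfinite(ssq):
            scored.append((ssq, x0))
    if not scored:
        raise FitError("objective not finite at any start point")
    scored.sort(key=lambda s: s[0])

    best = None
    converged = False
    for ssq0, x0 in scored[:n_refine]:
        sol = least_squares(
            fun,
            np.clip(x0, lb, ub),
            bounds=(lb, ub),
            method="trf",
            diff_step=1e-4,
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=max_nfev * (len(params) + 1),
        )
        ssq = float(sol.fun @ sol.fun)
        if best is None or ssq < best[0]:
            best = (ssq, sol.x)
            converged = bool(sol.status > 0)

    ssq, x_best = best
    estimates = dict(zip(paths, 10.0 ** x_best))
    at_bound = {
        p.path: bool(
            np.isclose(x, lo, atol=1e-4) or np.isclose(x, hi, atol=1e-4)
        )
        for p, x, lo, hi in zip(params, x_best, lb, ub)
    }
    fold = predictive_check_values(template, estimates, data)
    uninformed = [p for p in paths if _tissue_of(p) and _tissue_of(p) not in fitted_tissues]
    if uninformed:
        warnings.warn(
            f"no observations for tissues of fitted parameters: {uninformed}",
            stacklevel=2,
        )
    return FitResult(
        estimates=estimates,
        objective_value=ssq,
        converged=converged,
        at_bound_flags=at_bound,
        fold_errors=fold,
        n_objective_evals=evals,
    )


def _tissue_of(path: str) -> Optional[str]:
    head, _, tail = path.partition(".")
    return tail if head in ("partition_coefficients", "permeabilities") else None


def predictive_check_values(
    template: FitTemplate, estimates: dict[str, float], data: Sequence[TKObservation]
) -> dict[tuple, float]:
    """Cmax fold errors (predicted/observed) per (route, dose, tissue) arm."""
    arms = _arms(list(data))
    sims = _simulate_arms(template, estimates, arms)
    folds: dict[tuple, float] = {}
    for (route, dose), obs_list in arms.items():
        sim = sims[(route, dose)]
        tissues = {o.tissue for o in obs_list}
        for tissue in tissues:
            t_obs = [o.time for o in obs_list if o.tissue == tissue]
            window = (sim.time >= min(t_obs)) & (sim.time <= max(t_obs))
            pred_cmax = float(sim.concentrations[tissue][window].max())
            obs_cmax = max(o.concentration for o in obs_list if o.tissue == tissue)
            folds[(route, dose, tissue)] = pred_cmax / max(obs_cmax, EPS_FLOOR_UM)
    return folds


def predictive_check(
    fit: FitResult, data: Sequence[TKObservation], template: FitTemplate
) -> dict[tuple, float]:
    """Fold errors of a converged fit against (possibly held-out) observations."""
    if not fit.converged:
        raise FitError("predictive check requires a converged fit")
    return predictive_check_values(template, fit.estimates, data)


def read_observations(path, molecular_weight: Optional[float] = None) -> list[TKObservation]:
    """Read the TK CSV dialect (study,route,dose_mg_per_kg,tissue,time_min,
    concentration,unit); unit 'uM' or 'ng_per_ml' (the latter needs the
    molecular weight for conversion)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, r in df.iterrows():
        conc = float(r["concentration"])
        unit = str(r["unit"])
        if unit == "ng_per_ml":
            if molecular_weight is None:
                raise ValueError("molecular_weight required to convert ng_per_ml")
            conc = mass_to_molar(conc, molecular_weight)
        elif unit != "uM":
            raise ValueError(f"unsupported concentration unit: {unit!r}")
        out.append(
            TKObservation(
                time=float(r["time_min"]),
                dose=float(r["dose_mg_per_kg"]),
                route=str(r["route"]),
                tissue=str(r["tissue"]),
                concentration=conc,
                study_label=str(r["study"]),
            )
        )
    return out


def write_observations(data: Sequence[TKObservation], path) -> None:
    pd.DataFrame(
        {
            "study": [o.study_label for o in data],
            "route": [o.route for o in data],
            "dose_mg_per_kg": [o.dose for o in data],
            "tissue": [o.tissue for o in data],
            "time_min": [o.time for o in data],
            "concentration": [o.concentration for o in data],
            "unit": ["uM"] * len(data),
        }
    ).to_csv(path, index=False)
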