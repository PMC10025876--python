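"""Synthetic rat toxicokinetic datasets for fitting and validation tests.

Emulates the structure of the adult-rat tissue TK studies used for model
calibration: plasma, brain, liver, fat, and muscle sampled over 0.5-96 h
after single oral doses of 1, 2, and 10 mg/kg and an IV dose of 0.5 mg/kg,
with a 14-day tail point for fat (slow adipose kinetics).  Observations are
the model's own predictions under known "truth" parameters, perturbed with
mean-preserving multiplicative lognormal noise and censored below the limit
of quantification.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .compound import load_fittable_parameters
from .fitting import TKObservation, apply_parameters
from .pbk_core import DosingRegimen, MetabolismSpec, build_model, simulate
from .physiology import PhysiologySet

DEFAULT_TISSUES = ("plasma", "brain", "liver", "fat", "muscle")
DEFAULT_DOSES = ((1.0, "oral"), (2.0, "oral"), (10.0, "oral"), (0.5, "iv"))


class SyntheticStudyDesign(BaseModel):
    """Sampling design for one synthetic study."""

    doses: list[tuple[float, str]] = Field(default=list(DEFAULT_DOSES))
    tissues: list[str] = Field(default=list(DEFAULT_TISSUES))
    sampling_times: list[float] = Field(description="min")
    noise_cv: float = Field(ge=0.0, default=0.2)
    lloq: float = Field(default=1e-5, description="µM")
    seed: int = 0
    fat_tail_time: float = Field(default=20160.0, description="min; extra fat point")

    @model_validator(mode="after")
    def _check_times(self):
        t = np.asarray(self.sampling_times)
        if t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("sampling_times must be non-negative and strictly increasing")
        return self

    @classmethod
    def default(cls, seed: int = 0, noise_cv: float = 0.2) -> "SyntheticStudyDesign":
        """0.5-96 h log-spaced grid plus the 14-day adipose tail point."""
        times = np.unique(np.round(np.geomspace(30.0, 5760.0, 10)))
        return cls(sampling_times=list(times), seed=seed, noise_cv=noise_cv)


def _check_truth_within_bounds(truth_params: dict[str, float]) -> None:
    bounds = {p.path: (p.lower_bound, p.upper_bound) for p in load_fittable_parameters()}
    for path, value in truth_params.items():
        if path in bounds:
            lo, hi = bounds[path]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"truth parameter {path!r}={value} outside fitting bounds [{lo}, {hi}]"
                )


def generate_tk_dataset(
    truth_params: dict[str, float],
    design: SyntheticStudyDesign,
    phys: PhysiologySet,
    compound,
    metabolism: Sequence[MetabolismSpec],
    *,
    absorption_scale: float = 1.0,
) -> list[TKObservation]:
    """Simulate the truth model at every design arm and sample noisy observations.

    Noise is multiplicative lognormal with the design CV (mean-preserving);
    values below the LLOQ are censored (dropped).  Deterministic per seed.
    """
    _check_truth_within_bounds(truth_params)
    if not (0.0 < absorption_scale <= 1.0):
        raise ValueError(f"absorption_scale must be in (0, 1], got {absorption_scale}")
    compound, base_regimen, metabolism = apply_parameters(
        compound, DosingRegimen(route="oral", dose=1.0), list(metabolism), truth_params
    )
    if absorption_scale < 1.0:
        compound = compound.model_copy(
            update={
                "papp_ab": compound.papp_ab * absorption_scale,
                "fraction_absorbed_cap": compound.fraction_absorbed_cap * absorption_scale,
            }
        )
    rng = np.random.default_rng(design.seed)
    sigma2 = np.log1p(design.noise_cv**2)
    out: list[TKObservation] = []
    for dose, route in design.doses:
        reg = base_regimen.model_copy(update={"route": route, "dose": dose})
        model = build_model(phys, compound, metabolism, reg)
        times = np.asarray(design.sampling_times, dtype=float)
        t_last = design.fat_tail_time if "fat" in design.tissues else times[-1]
        duration = max(times[-1], t_last) * 1.02 / 1440.0
        sim = simulate(
            model,
            duration,
            rtol=1e-8,
            atol=1e-12,
            points_per_interval=120,
            extra_times=np.concatenate([times, [design.fat_tail_time], np.geomspace(1.0, duration * 1440.0, 80)]),
        )
        for tissue in design.tissues:
            t_obs = list(times) + ([design.fat_tail_time] if tissue == "fat" else [])
            for t in t_obs:
                true_val = float(np.interp(t, sim.time, sim.concentrations[tissue]))
                if design.noise_cv > 0:
                    noise = np.exp(rng.normal(-0.5 * sigma2, np.sqrt(sigma2)))
                else:
                    noise = 1.0
                obs = true_val * noise
                if obs < design.lloq:
                    continue
                out.append(
                    TKObservation(
                        time=t,
                        dose=dose,
                        route=route,
                        tissue=tissue,
                        concentration=obs,
                        study_label=f"synthetic-{route}-{dose:g}mgkg",
                    )
                )
    return out


def generate_low_absorption_variant(
    truth_params: dict[str, float],
    design: SyntheticStudyDesign,
    phys: PhysiologySet,
    compound,
    metabolism: Sequence[MetabolismSpec],
    absorption_scale: float = 0.3,
) -> list[TKObservation]:
    """Reduced-absorption dataset (slower, capped uptake), emulating oral
    dosing in a vehicle with poorer gastrointestinal availability.  A model
    calibrated on the standard-vehicle data over-predicts these observations."""
    return generate_tk_dataset(
        truth_params, design, phys, compound, metabolism, absorption_scale=absorption_scale
    )


def default_truth_parameters() -> dict[str, float]:
    """Packaged-default values of the default fittable paths (fit 'truth')."""
    from .fitting import DEFAULT_FIT_PATHS

    tmpl = {p.path: p.optimal for p in load_fittable_parameters()}
    return {path: tmpl[path] for path in DEFAULT_FIT_PATHS}
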