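"""Compound physicochemistry, plasma binding, and partitioning logic.

The packaged compound is deltamethrin (DLT), a highly lipophilic pyrethroid
(measured logKow 6.4).  Standard composition-based partitioning rules break
down at such lipophilicities, so the model works with an *effective*
lipophilicity: the measured logKow divided by a fitted correction factor
(6.4 / 3.6 = 1.78, the value that reproduces both published fit outputs
simultaneously).  Tissues with a directly fitted partition coefficient
(brain, fat, liver, muscle) bypass the composition rule entirely.

For the remaining organs the tissue:plasma partition coefficient follows a
lipid/water composition rule in which tissue equilibrates with the unbound
plasma fraction:

    K = fup * (f_lipid * 10**logKow_eff + f_water) / f_water_plasma

which is monotone increasing in effective lipophilicity for lipid-containing
tissues and reduces to a pure water/plasma-water term for lipid-free tissue.
"""
from __future__ import annotations

import math
from importlib import resources
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError

#: organs whose partition coefficients come from the rat fit, not the rule
FITTED_PARTITION_ORGANS = ("brain", "fat", "liver", "muscle")


def _data_path(name: str):
    return resources.files("fetalpbk.data").joinpath(name)


class CompoundSpec(BaseModel):
    """Physicochemistry, binding, absorption, and distribution parameters."""

    name: str
    molecular_weight: float = Field(gt=0.0, description="g/mol")
    logKow_measured: float
    lipophilicity_correction: float = Field(ge=1.0)
    fraction_unbound_plasma: float = Field(gt=0.0, le=1.0)
    solubility: float = Field(gt=0.0, description="mg/L")
    papp_ab: float = Field(gt=0.0, description="cm/s, apical->basolateral")
    papp_ba: float = Field(gt=0.0, description="cm/s, basolateral->apical")
    fraction_absorbed_cap: float = Field(gt=0.0, le=1.0)
    partition_coefficients: dict[str, float]
    permeabilities: dict[str, float] = Field(description="cm/min per organ")

    @model_validator(mode="after")
    def _check_positive_maps(self):
        for organ, k in self.partition_coefficients.items():
            if k <= 0:
                raise ConfigurationError(f"partition_coefficients.{organ} must be > 0, got {k}")
        for organ, p in self.permeabilities.items():
            if p <= 0:
                raise ConfigurationError(f"permeabilities.{organ} must be > 0, got {p}")
        return self

    @property
    def effective_logkow(self) -> float:
        return effective_lipophilicity(self.logKow_measured, self.lipophilicity_correction)


class FittableParameter(BaseModel):
    """One estimable parameter with its fitting bounds."""

    path: str
    optimal: float
    lower_bound: float
    upper_bound: float
    unit: str = ""

    @model_validator(mode="after")
    def _check_bounds(self):
        if not (self.lower_bound <= self.optimal <= self.upper_bound):
            raise ConfigurationError(
                f"{self.path}: optimal {self.optimal} outside bounds "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )
        return self


def effective_lipophilicity(logkow_measured: float, lipophilicity_correction: float) -> float:
    """Effective logKow entering partitioning: measured / correction.

    The correction factor is bounded below by 1 (no correction).
    """
    if lipophilicity_correction < 1.0:
        raise ValueError(
            f"lipophilicity_correction must be >= 1, got {lipophilicity_correction}"
        )
    return logkow_measured / lipophilicity_correction


def predict_partition(
    organ: str,
    effective_logkow: float,
    fraction_unbound_plasma: float,
    tissue_composition: dict[str, dict[str, float]],
) -> float:
    """Composition-rule tissue:plasma partition coefficient for non-fitted organs."""
    if organ not in tissue_composition:
        raise ConfigurationError(f"no tissue composition entry for organ {organ!r}")
    if "plasma" not in tissue_composition:
        raise ConfigurationError("tissue composition table lacks the 'plasma' row")
    comp = tissue_composition[organ]
    plasma = tissue_composition["plasma"]
    p = 10.0 ** effective_logkow
    return fraction_unbound_plasma * (comp["f_lipid"] * p + comp["f_water"]) / plasma["f_water"]


def mass_to_molar(concentration_ng_per_ml: float, molecular_weight: float) -> float:
    """Convert ng/mL to µM (ng/mL divided by g/mol is µmol/L)."""
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    return concentration_ng_per_ml / molecular_weight


def molar_to_mass(concentration_um: float, molecular_weight: float) -> float:
    """Convert µM back to ng/mL (inverse of :func:`mass_to_molar`)."""
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    return concentration_um * molecular_weight


def load_tissue_composition(stage: str = "") -> dict[str, dict[str, float]]:
    """Lipid/water fractions per organ; fetal tissue rows are stage-specific."""
    df = pd.read_csv(_data_path("tissue_composition.csv"), keep_default_na=False)
    out: dict[str, dict[str, float]] = {}
    for _, r in df.iterrows():
        if r["stage"] not in ("", stage):
            continue
        out[r["organ"]] = {"f_lipid": float(r["f_lipid"]), "f_water": float(r["f_water"])}
    return out


def partition_coefficient(
    compound: CompoundSpec, organ: str, tissue_composition: dict[str, dict[str, float]]
) -> float:
    """Fitted value when available, composition rule otherwise."""
    if organ in compound.partition_coefficients:
        return compound.partition_coefficients[organ]
    return predict_partition(
        organ,
        compound.effective_logkow,
        compound.fraction_unbound_plasma,
        tissue_composition,
    )


def load_compound(path: Optional[str] = None) -> CompoundSpec:
    """Load a compound definition (packaged deltamethrin by default)."""
    if path is None:
        text = _data_path("deltamethrin.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    try:
        return CompoundSpec(
            name=raw["name"],
            molecular_weight=raw["molecular_weight_g_per_mol"],
            logKow_measured=raw["logkow_measured"],
            lipophilicity_correction=raw["lipophilicity_correction"],
            fraction_unbound_plasma=raw["fraction_unbound_plasma"],
            solubility=raw["solubility_mg_per_l"],
            papp_ab=raw["papp_ab_cm_per_s"],
            papp_ba=raw["papp_ba_cm_per_s"],
            fraction_absorbed_cap=raw["fraction_absorbed_cap"],
            partition_coefficients=raw["partition_coefficients"],
            permeabilities=raw["permeabilities_cm_per_min"],
        )
    except KeyError as exc:
        raise ConfigurationError(f"compound file missing field: {exc}") from exc


def load_fittable_parameters(path: Optional[str] = None) -> list[FittableParameter]:
    """The full fittable-parameter template (path, optimum, bounds, unit)."""
    if path is None:
        text = _data_path("fit_parameters.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [
        FittableParameter(
            path=r["path"],
            optimal=r["optimal"],
            lower_bound=r["lower"],
            upper_bound=r["upper"],
            unit=r.get("unit", ""),
        )
        for r in raw
    ]


def solubility_to_um(solubility_mg_per_l: float, molecular_weight: float) -> float:
    """mg/L to µM."""
    return 1000.0 * solubility_mg_per_l / molecular_weight


def check_lipophilicity_consistency(compound: CompoundSpec, printed_value: float = 1.8) -> bool:
    """True when measured/correction reproduces the fitted effective value to rounding."""
    return math.isclose(round(compound.effective_logkow, 1), printed_value, abs_tol=1e-9)
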