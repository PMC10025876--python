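"""Reference anatomy and physiology for the whole-body kinetic model.

Provides species-level organ volumes, blood flows, and exchange surface areas
for the adult rat, the adult (non-pregnant) human, and the pregnant human at
gestational week 20 or 40, compiled from standard literature reference tables
and shipped as versioned CSV data files.  The pregnant physiology adds the
maternal-fetal sub-circuit: a maternally perfused placenta that exchanges with
a fetal plasma compartment by passive diffusion, and a lumped fetal tissue
compartment downstream of fetal plasma.  The fetus does not grow during a
simulation; gestational age is fixed per run.

Population variability is modeled as mean-preserving lognormal scatter on
organ volumes, blood flows, and metabolic capacity.  Cardiac output is always
recomputed as the sum of organ blood flows, so flow conservation holds in
every sampled individual by construction.
"""
from __future__ import annotations

from importlib import resources
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError

FETAL_ORGANS = frozenset({"placenta", "fetal_plasma", "fetal_tissue"})
ORGAN_VOCABULARY = frozenset(
    {
        "venous",
        "arterial",
        "brain",
        "liver",
        "fat",
        "muscle",
        "gut_lumen",
        "gut_tissue",
        "kidney",
        "rest_of_body",
        "placenta",
        "fetal_plasma",
        "fetal_tissue",
    }
)


def _data_path(name: str):
    return resources.files("fetalpbk.data").joinpath(name)


class OrganSpec(BaseModel):
    """One compartment of the reference anatomy.

    ``blood_flow`` is the arterial supply in L/min (for the liver: hepatic
    artery only; the portal inflow arrives via the gut).  Diffusion-only
    compartments (gut lumen, fetal plasma, fetal tissue) carry zero flow.
    ``exchange_surface_area`` is the vascular-tissue exchange area in dm².
    """

    model_config = ConfigDict(frozen=False)

    name: str
    volume: float = Field(gt=0.0, description="L")
    blood_flow: float = Field(ge=0.0, description="L/min")
    exchange_surface_area: float = Field(ge=0.0, description="dm^2")
    is_fetal: bool = False

    @model_validator(mode="after")
    def _check_name(self):
        if self.name not in ORGAN_VOCABULARY:
            raise ConfigurationError(f"unknown organ name: {self.name!r}")
        return self


class PhysiologySet(BaseModel):
    """A complete, internally consistent anatomy for one individual."""

    species: Literal["rat", "human"]
    body_weight: float = Field(gt=0.0, description="kg")
    gestational_age: Optional[int] = None
    cardiac_output: float = Field(gt=0.0, description="L/min")
    organs: list[OrganSpec]
    liver_mass: float = Field(gt=0.0, description="g")
    metabolic_scale: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check_consistency(self):
        names = {o.name for o in self.organs}
        if self.gestational_age is not None:
            if self.species != "human":
                raise ConfigurationError(
                    "gestational_age requires species='human' "
                    f"(got species={self.species!r})"
                )
            missing = FETAL_ORGANS - names
            if missing:
                raise ConfigurationError(
                    f"pregnant physiology lacks fetal organs: {sorted(missing)}"
                )
        else:
            present = FETAL_ORGANS & names
            if present:
                raise ConfigurationError(
                    f"non-pregnant physiology contains fetal organs: {sorted(present)}"
                )
        total_flow = sum(o.blood_flow for o in self.organs)
        if abs(total_flow - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ConfigurationError(
                "organ blood flows do not sum to cardiac output "
                f"({total_flow!r} vs {self.cardiac_output!r})"
            )
        return self

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise ConfigurationError(f"organ {name!r} not present in this physiology")

    def has_organ(self, name: str) -> bool:
        return any(o.name == name for o in self.organs)

    @property
    def stage(self) -> str:
        return "" if self.gestational_age is None else f"gw{self.gestational_age}"


class VariabilityModel(BaseModel):
    """Lognormal inter-individual variability on physiology parameters.

    ``cv_map`` maps parameter paths (``organs.<name>.volume``,
    ``organs.<name>.blood_flow``, ``metabolic_scale``, ``liver_mass``,
    ``body_weight``) to coefficients of variation.  ``cardiac_output`` is not
    a valid path: it is derived from the sampled flows.
    """

    cv_map: dict[str, float]
    distribution: Literal["lognormal"] = "lognormal"
    seed: int = 0

    @model_validator(mode="after")
    def _check_cvs(self):
        for path, cv in self.cv_map.items():
            if not (0.0 <= cv < 1.0):
                raise ConfigurationError(f"CV for {path!r} must be in [0, 1), got {cv}")
            if path == "cardiac_output":
                raise ConfigurationError(
                    "cardiac_output cannot be sampled directly; it is derived "
                    "from the sampled organ blood flows"
                )
        return self

    @classmethod
    def default(cls, seed: int = 0, cv: float = 0.2) -> "VariabilityModel":
        """CV 0.2 on all organ volumes/flows and on metabolic capacity."""
        cv_map = {"metabolic_scale": cv}
        for organ in sorted(ORGAN_VOCABULARY):
            cv_map[f"organs.{organ}.volume"] = cv
            cv_map[f"organs.{organ}.blood_flow"] = cv
        return cls(cv_map=cv_map, seed=seed)


def _load_tables():
    organs = pd.read_csv(_data_path("physiology.csv"), keep_default_na=False)
    bodies = pd.read_csv(_data_path("reference_bodies.csv"), keep_default_na=False)
    return organs, bodies


def build_physiology(
    species: str,
    body_weight: float | None = None,
    gestational_age: int | None = None,
) -> PhysiologySet:
    """Assemble a :class:`PhysiologySet` from the packaged reference tables.

    Maternal organ volumes and flows scale linearly with ``body_weight``
    relative to the table's reference body weight; fetal compartments and the
    placenta are set by gestational age alone.  ``gestational_age`` must be
    absent (non-pregnant) or 20 or 40 weeks.
    """
    if species not in ("rat", "human"):
        raise ConfigurationError(f"unsupported species: {species!r}")
    if gestational_age is not None:
        if species != "human":
            raise ConfigurationError(
                f"gestational_age is only supported for humans, got species={species!r}"
            )
        if gestational_age not in (20, 40):
            raise ConfigurationError(
                f"gestational_age must be 20 or 40 weeks, got {gestational_age!r}"
            )
    stage = "" if gestational_age is None else f"gw{gestational_age}"
    organs_tbl, bodies_tbl = _load_tables()
    sel = (organs_tbl["species"] == species) & (organs_tbl["stage"] == stage)
    rows = organs_tbl[sel]
    if rows.empty:
        raise ConfigurationError(f"no reference physiology for {species!r} stage {stage!r}")
    ref = bodies_tbl[(bodies_tbl["species"] == species) & (bodies_tbl["stage"] == stage)]
    ref_bw = float(ref["body_weight_kg"].iloc[0])
    liver_mass_ref = float(ref["liver_mass_g"].iloc[0])
    if body_weight is None:
        body_weight = ref_bw
    scale = body_weight / ref_bw

    organs: list[OrganSpec] = []
    for _, r in rows.iterrows():
        fetal = bool(int(r["is_fetal"]))
        s = 1.0 if (fetal or r["organ"] == "placenta") else scale
        organs.append(
            OrganSpec(
                name=r["organ"],
                volume=float(r["volume_L"]) * s,
                blood_flow=float(r["blood_flow_L_per_min"]) * s,
                exchange_surface_area=float(r["surface_area_dm2"]) * s,
                is_fetal=fetal,
            )
        )
    cardiac_output = sum(o.blood_flow for o in organs)
    return PhysiologySet(
        species=species,
        body_weight=body_weight,
        gestational_age=gestational_age,
        cardiac_output=cardiac_output,
        organs=organs,
        liver_mass=liver_mass_ref * scale,
    )


def _apply_factor(phys_dict: dict, path: str, factor: float) -> None:
    parts = path.split(".")
    if parts[0] == "organs":
        _, organ, field = parts
        for o in phys_dict["organs"]:
            if o["name"] == organ:
                o[field] *= factor
        return
    if len(parts) == 1 and parts[0] in ("metabolic_scale", "liver_mass", "body_weight"):
        phys_dict[parts[0]] *= factor
        return
    raise ConfigurationError(f"unknown variability parameter path: {path!r}")


def sample_population(
    base: PhysiologySet, model: VariabilityModel, n: int
) -> list[PhysiologySet]:
    """Draw ``n`` individuals around ``base``.

    Each parameter p is multiplied by exp(eps) with eps ~ N(-sigma^2/2, sigma^2)
    and sigma^2 = ln(1 + CV^2), so the arithmetic mean of p is preserved and
    its coefficient of variation equals the requested CV.  Identical seeds give
    bit-identical populations.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = np.random.default_rng(model.seed)
    paths = sorted(model.cv_map)  # stable draw order
    out: list[PhysiologySet] = []
    for _ in range(n):
        d = base.model_dump()
        for path in paths:
            cv = model.cv_map[path]
            if cv == 0.0:
                continue
            if path.startswith("organs.") and not base.has_organ(path.split(".")[1]):
                continue
            sigma2 = np.log1p(cv * cv)
            eps = rng.normal(-0.5 * sigma2, np.sqrt(sigma2))
            _apply_factor(d, path, float(np.exp(eps)))
        d["cardiac_output"] = sum(o["blood_flow"] for o in d["organs"])
        out.append(PhysiologySet.model_validate(d))
    return out
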