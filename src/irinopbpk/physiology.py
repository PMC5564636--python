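"""Reference virtual adult and virtual-population generation.

The whole-body model uses a standard reference-adult anatomy: organ volumes,
regional blood flows and organ composition in the style of the ICRP
reference-man compilations, with a small, poorly perfused, acidic tumor
compartment added. Anthropometric scaling follows a simple documented rule:
structural organs scale with the height-predicted normal weight
(BMI-preserving, W ∝ H²) and any weight excess over that prediction is
assigned to adipose tissue, so heavier subjects at fixed height become
fatter rather than uniformly larger. Organ blood flows scale with organ
volume and cardiac output is their sum, so flow balance holds for every
generated individual by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Organ",
    "VirtualIndividual",
    "PopulationSpec",
    "build_reference_individual",
    "generate_population",
    "population_to_frame",
    "REFERENCE_ANATOMY",
    "SYSTEMIC_ORGANS",
]


class ValidationError(ValueError):
    """Raised for non-physiologic anthropometrics or invalid population specs."""


@dataclass(frozen=True)
class Organ:
    """One perfusion-limited compartment."""

    volume: float       # L
    blood_flow: float   # L/min
    water_fraction: float
    lipid_fraction: float


@dataclass(frozen=True)
class VirtualIndividual:
    """Anthropometrics plus the scaled organ set of one virtual subject."""

    sex: str
    age: float                 # years
    body_weight: float         # kg
    height: float              # cm
    body_surface_area: float   # m^2
    hematocrit: float
    gfr: float                 # ml/min
    organs: Mapping[str, Organ]
    tumor_ph: float = 6.8

    @property
    def cardiac_output(self) -> float:
        """Total systemic blood flow in L/min (equals pulmonary flow)."""
        return sum(self.organs[o].blood_flow for o in SYSTEMIC_ORGANS)

    def validate(self) -> None:
        for name, organ in self.organs.items():
            if organ.volume <= 0 or organ.blood_flow <= 0:
                raise ValidationError(f"organ {name!r} has non-positive volume/flow")
        co = self.cardiac_output
        if abs(self.organs["lung"].blood_flow - co) > 1e-6 * co:
            raise ValidationError("pulmonary flow does not balance systemic flows")


@dataclass(frozen=True)
class PopulationSpec:
    """Stochastic description of a virtual population.

    Coefficients of variation are log-normal CVs on the multiplicative
    scale; the seed is mandatory so population generation is a pure
    function of the spec.
    """

    n_individuals: int
    random_seed: int
    female_fraction: float = 0.5
    age_range: tuple[float, float] = (40.0, 65.0)
    weight_cv: float = 0.15
    height_cv: float = 0.05
    organ_volume_cv: float = 0.10
    organ_flow_cv: float = 0.10
    gfr_cv: float = 0.20

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValidationError("female_fraction must lie in [0, 1]")
        for cv in (self.weight_cv, self.height_cv, self.organ_volume_cv,
                   self.organ_flow_cv, self.gfr_cv):
            if cv < 0:
                raise ValidationError("coefficients of variation must be >= 0")


# Reference anatomy: organ volumes (L) for the reference male, fraction of
# cardiac output, and tissue water/lipid content. Volumes and flow
# fractions follow ICRP-style reference-adult compilations; composition
# values are the ones commonly used by homogenate partition models.
# Flow fractions are renormalized at build time so systemic flows sum
# exactly to cardiac output.
REFERENCE_ANATOMY: dict[str, dict[str, float]] = {
    #              V_L    f_CO    f_water f_lipid
    "lung":     {"v": 0.50, "f": 1.000, "w": 0.80, "l": 0.013},
    "heart":    {"v": 0.33, "f": 0.040, "w": 0.73, "l": 0.025},
    "brain":    {"v": 1.45, "f": 0.120, "w": 0.77, "l": 0.051},
    "muscle":   {"v": 29.0, "f": 0.170, "w": 0.76, "l": 0.022},
    "adipose":  {"v": 12.0, "f": 0.050, "w": 0.18, "l": 0.790},
    "skin":     {"v": 3.30, "f": 0.050, "w": 0.72, "l": 0.051},
    "bone":     {"v": 10.5, "f": 0.050, "w": 0.43, "l": 0.074},
    "liver":    {"v": 1.80, "f": 0.065, "w": 0.75, "l": 0.069},
    "spleen":   {"v": 0.15, "f": 0.030, "w": 0.78, "l": 0.020},
    "gut":      {"v": 1.20, "f": 0.160, "w": 0.75, "l": 0.049},
    "kidney":   {"v": 0.31, "f": 0.190, "w": 0.78, "l": 0.028},
    "arterial_blood": {"v": 1.80, "f": 0.0, "w": 0.82, "l": 0.004},
    "venous_blood":   {"v": 3.60, "f": 0.0, "w": 0.82, "l": 0.004},
    "tumor":    {"v": 0.10, "f": 0.0, "w": 0.80, "l": 0.020},
}

# Organs whose blood flows sum to cardiac output. Lung carries the whole
# pulmonary flow and the blood pools are not perfused compartments.
SYSTEMIC_ORGANS: tuple[str, ...] = (
    "heart", "brain", "muscle", "adipose", "skin", "bone",
    "liver", "spleen", "gut", "kidney", "tumor",
)

_SEX_REFERENCE = {
    "male": {"weight": 73.0, "height": 176.0, "co": 6.0, "gfr": 110.0,
             "hematocrit": 0.45, "adipose": 12.0},
    "female": {"weight": 60.0, "height": 163.0, "co": 5.4, "gfr": 95.0,
               "hematocrit": 0.40, "adipose": 16.0},
}

# Default tumor compartment: small, poorly perfused, acidic.
TUMOR_DEFAULTS = {"volume": 0.10, "blood_flow": 0.010, "ph": 6.8}

_WEIGHT_BOUNDS = (30.0, 200.0)
_HEIGHT_BOUNDS = (120.0, 220.0)
_AGE_BOUNDS = (18.0, 95.0)


def body_surface_area(weight: float, height: float) -> float:
    """DuBois-DuBois BSA in m² from weight (kg) and height (cm)."""
    return 0.007184 * weight**0.425 * height**0.725


def build_reference_individual(
    sex: str = "male",
    age: float = 55.0,
    body_weight: float | None = None,
    height: float | None = None,
    tumor_volume: float = TUMOR_DEFAULTS["volume"],
    tumor_blood_flow: float = TUMOR_DEFAULTS["blood_flow"],
    tumor_ph: float = TUMOR_DEFAULTS["ph"],
    volume_scale: Mapping[str, float] | None = None,
    flow_scale: Mapping[str, float] | None = None,
    gfr_scale: float = 1.0,
) -> VirtualIndividual:
    """Construct one virtual adult with the documented reference anatomy.

    Structural organ volumes scale with the BMI-preserving predicted weight
    ``W_norm = W_ref * (H / H_ref)**2``; excess weight over ``W_norm`` goes
    to adipose tissue (1 kg ~ 1 L). Organ flows scale with organ volume and
    cardiac output is recomputed as their sum. ``volume_scale``/``flow_scale``
    apply optional per-organ multiplicative perturbations (used by the
    population generator).

    Raises
    ------
    ValidationError
        If sex is unknown or anthropometrics are outside documented
        physiologic bounds (weight 30-200 kg, height 120-220 cm,
        age 18-95 y).
    """
    if sex not in _SEX_REFERENCE:
        raise ValidationError(f"unknown sex {sex!r}")
    ref = _SEX_REFERENCE[sex]
    if body_weight is None:
        body_weight = ref["weight"]
    if height is None:
        height = ref["height"]
    if not (_WEIGHT_BOUNDS[0] <= body_weight <= _WEIGHT_BOUNDS[1]):
        raise ValidationError(f"body_weight {body_weight} kg outside physiologic bounds")
    if not (_HEIGHT_BOUNDS[0] <= height <= _HEIGHT_BOUNDS[1]):
        raise ValidationError(f"height {height} cm outside physiologic bounds")
    if not (_AGE_BOUNDS[0] <= age <= _AGE_BOUNDS[1]):
        raise ValidationError(f"age {age} y outside documented bounds")

    h_ratio = height / ref["height"]
    w_norm = ref["weight"] * h_ratio**2
    structural_scale = w_norm / ref["weight"]
    excess = body_weight - w_norm

    vol_scale = dict(volume_scale or {})
    flw_scale = dict(flow_scale or {})

    # renormalize systemic flow fractions so they sum to 1
    f_total = sum(REFERENCE_ANATOMY[o]["f"] for o in SYSTEMIC_ORGANS
                  if o != "tumor")
    organs: dict[str, Organ] = {}
    flows: dict[str, float] = {}
    for name, entry in REFERENCE_ANATOMY.items():
        if name == "adipose":
            v_ref = ref["adipose"]
            volume = max(0.5, v_ref * structural_scale + excess)
        elif name == "tumor":
            v_ref = tumor_volume
            volume = tumor_volume
        else:
            v_ref = entry["v"]
            volume = v_ref * structural_scale
        volume *= vol_scale.get(name, 1.0)
        if name == "tumor":
            flow = tumor_blood_flow
        elif name in SYSTEMIC_ORGANS:
            # flow tracks the (possibly perturbed) organ volume
            flow = (entry["f"] / f_total) * ref["co"] * (volume / v_ref)
        else:
            flow = 0.0  # lung and blood pools filled in below
        flow *= flw_scale.get(name, 1.0)
        flows[name] = flow
        organs[name] = Organ(volume=volume, blood_flow=flow,
                             water_fraction=entry["w"],
                             lipid_fraction=entry["l"])

    co = sum(flows[o] for o in SYSTEMIC_ORGANS)
    for pool in ("lung", "arterial_blood", "venous_blood"):
        organs[pool] = replace(organs[pool], blood_flow=co)

    individual = VirtualIndividual(
        sex=sex,
        age=age,
        body_weight=body_weight,
        height=height,
        body_surface_area=body_surface_area(body_weight, height),
        hematocrit=ref["hematocrit"],
        gfr=ref["gfr"] * (body_surface_area(body_weight, height) / 1.73) * gfr_scale,
        organs=organs,
        tumor_ph=tumor_ph,
    )
    individual.validate()
    return individual


def generate_population(spec: PopulationSpec) -> list[VirtualIndividual]:
    """Draw a reproducible virtual population from ``spec``.

    Sex counts follow deterministic rounding of ``female_fraction``; ages
    are uniform over ``age_range``; weight and height are log-normal around
    the sex-specific reference with the spec CVs; per-organ volume and flow
    perturbations and a GFR perturbation are independent log-normals.
    """
    rng = np.random.default_rng(spec.random_seed)
    n_female = round(spec.n_individuals * spec.female_fraction)
    sexes = ["female"] * n_female + ["male"] * (spec.n_individuals - n_female)

    organ_names = list(REFERENCE_ANATOMY)
    population: list[VirtualIndividual] = []
    for sex in sexes:
        ref = _SEX_REFERENCE[sex]
        age = rng.uniform(*spec.age_range)
        weight = _lognormal(rng, ref["weight"], spec.weight_cv)
        height = _lognormal(rng, ref["height"], spec.height_cv)
        weight = float(np.clip(weight, *_WEIGHT_BOUNDS))
        height = float(np.clip(height, *_HEIGHT_BOUNDS))
        vol_scale = {o: _lognormal(rng, 1.0, spec.organ_volume_cv)
                     for o in organ_names}
        flow_scale = {o: _lognormal(rng, 1.0, spec.organ_flow_cv)
                      for o in organ_names}
        gfr_scale = _lognormal(rng, 1.0, spec.gfr_cv)
        population.append(build_reference_individual(
            sex=sex, age=age, body_weight=weight, height=height,
            volume_scale=vol_scale, flow_scale=flow_scale,
            gfr_scale=gfr_scale,
        ))
    return population


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with arithmetic mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return mean
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def population_to_frame(population: Iterable[VirtualIndividual]) -> pd.DataFrame:
    """One row per individual: anthropometrics plus scalar organ parameters."""
    rows = []
    for i, ind in enumerate(population):
        row: dict[str, float | str] = {
            "subject": i,
            "sex": ind.sex,
            "age_y": ind.age,
            "body_weight_kg": ind.body_weight,
            "height_cm": ind.height,
            "bsa_m2": ind.body_surface_area,
            "hematocrit": ind.hematocrit,
            "gfr_ml_min": ind.gfr,
            "cardiac_output_l_min": ind.cardiac_output,
            "tumor_ph": ind.tumor_ph,
        }
        for name, organ in ind.organs.items():
            row[f"{name}_volume_l"] = organ.volume
            row[f"{name}_flow_l_min"] = organ.blood_flow
        rows.append(row)
    return pd.DataFrame(rows)
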