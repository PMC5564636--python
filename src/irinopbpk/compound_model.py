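"""Compound parameters, ionization/speciation, and tissue partition coefficients.

The camptothecins (irinotecan/CPT-11 and its active metabolite SN-38) are
zwitterionic molecules carrying one acidic and one basic site, and they
additionally interconvert between a closed, pharmacologically active lactone
ring and an open hydroxy-carboxylate form in a pH-dependent equilibrium.
This module holds the per-species physicochemical parameters, computes
ionization and lactone/carboxylate speciation, and derives the
tissue:plasma partition coefficients (Kp) that drive the perfusion-limited
whole-body model.

Speciation is a reporting quantity only: it deliberately does not feed back
into distribution or clearance, so simulated disposition is pH-invariant by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "CompoundProperties",
    "SpeciationState",
    "PartitionCoefficientSet",
    "ionized_fraction",
    "site_ionization",
    "lactone_fraction",
    "partition_coefficients",
    "TISSUE_BINDING_RATIO",
]

# Proportionality between tissue and plasma macromolecule binding used for
# the fu_tissue estimate in the homogenate Kp model (dimensionless).
# Default 0: tissue affinity is carried entirely by the lipid-partition
# term and plasma protein binding by fu_p.
TISSUE_BINDING_RATIO = 0.0

class InvalidInputError(ValueError):
    """Raised for non-finite or out-of-range scalar inputs."""


class ConfigurationError(ValueError):
    """Raised when required configuration entries are missing or inconsistent."""


@dataclass(frozen=True)
class CompoundProperties:
    """Physicochemical and clearance parameters of one chemical species.

    Parameters
    ----------
    name : str
        Species label, e.g. ``"CPT-11"``.
    molecular_weight : float
        Molar mass in g/mol.
    effective_molecular_weight : float
        Halogen-corrected molar mass in g/mol (carried for permeability
        extensions; unused by the perfusion-limited model).
    log_p : float
        log10 octanol:water partition coefficient of the neutral species.
    fraction_unbound : float
        Unbound fraction in plasma, in (0, 1].
    pka_acid : float
        pKa of the acidic site (pH units).
    pka_base : float
        pKa of the conjugate acid of the basic site (pH units).
    solubility_at_ph7 : float
        Aqueous solubility at pH 7 in mg/ml (informational).
    gfr_fraction : float
        Fraction of GFR available for renal filtration of unbound drug.
    specific_biliary_clearance : float
        Biliary clearance in ml/min per kg body weight.
    """

    name: str
    molecular_weight: float
    effective_molecular_weight: float
    log_p: float
    fraction_unbound: float
    pka_acid: float
    pka_base: float
    solubility_at_ph7: float = float("nan")
    gfr_fraction: float = 0.0
    specific_biliary_clearance: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_unbound <= 1.0):
            raise InvalidInputError(
                f"{self.name}: fraction_unbound must lie in (0, 1], "
                f"got {self.fraction_unbound}"
            )
        if self.molecular_weight <= 0:
            raise InvalidInputError(f"{self.name}: molecular_weight must be > 0")
        if self.effective_molecular_weight > self.molecular_weight:
            raise InvalidInputError(
                f"{self.name}: effective_molecular_weight exceeds molecular_weight"
            )
        if self.gfr_fraction < 0:
            raise InvalidInputError(f"{self.name}: gfr_fraction must be >= 0")
        if self.specific_biliary_clearance < 0:
            raise InvalidInputError(
                f"{self.name}: specific_biliary_clearance must be >= 0"
            )


@dataclass(frozen=True)
class SpeciationState:
    """Lactone/carboxylate/ionization split of one species at one pH."""

    ph: float
    lactone_fraction: float
    carboxylate_fraction: float
    ionized_fraction: float

    def __post_init__(self) -> None:
        if abs(self.lactone_fraction + self.carboxylate_fraction - 1.0) > 1e-12:
            raise InvalidInputError("lactone + carboxylate fractions must sum to 1")


@dataclass(frozen=True)
class PartitionCoefficientSet:
    """Tissue:plasma partition coefficients, one per organ."""

    compound: str
    kp: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for organ, value in self.kp.items():
            if not (value > 0):
                raise InvalidInputError(
                    f"Kp[{organ}] must be > 0, got {value}"
                )

    def __getitem__(self, organ: str) -> float:
        return self.kp[organ]


def _check_ph(ph: float) -> None:
    if not (isinstance(ph, (int, float)) and math.isfinite(ph)):
        raise InvalidInputError(f"pH must be finite, got {ph!r}")
    if not (0.0 < ph < 14.0):
        raise InvalidInputError(f"pH must lie in (0, 14), got {ph}")


def site_ionization(ph: float, props: CompoundProperties) -> tuple[float, float]:
    """Henderson-Hasselbalch ionized fraction of the acid and base sites.

    Returns ``(acid_ionized, base_ionized)``: the fraction of molecules
    whose acidic site is deprotonated and whose basic site is protonated,
    treating the two sites as independent.
    """
    _check_ph(ph)
    acid = 1.0 / (1.0 + 10.0 ** (props.pka_acid - ph))
    base = 1.0 / (1.0 + 10.0 ** (ph - props.pka_base))
    return acid, base


def ionized_fraction(ph: float, props: CompoundProperties) -> float:
    """Total ionized fraction of a zwitterionic acid/base pair at ``ph``.

    A molecule counts as ionized when at least one of the two sites carries
    a charge; with independent sites the neutral microstate has probability
    ``(1 - f_acid)(1 - f_base)``.
    """
    acid, base = site_ionization(ph, props)
    return 1.0 - (1.0 - acid) * (1.0 - base)


def lactone_fraction(
    ph: float,
    midpoint_ph: float = 6.5,
    hill_slope: float = 1.0,
    props: CompoundProperties | None = None,
) -> SpeciationState:
    """Sigmoidal lactone/carboxylate equilibrium as a function of pH.

    The closed lactone ring dominates at high pH and the open
    hydroxy-carboxylate at low pH (4-6); the transition is modelled as a
    Hill sigmoid with configurable midpoint and slope since no quantitative
    equilibrium constants are available for the in-vivo matrix.

    Note the direction: ``lactone_fraction`` *increases* with pH, matching
    the observed shift towards the lactone above pH 7.
    """
    _check_ph(ph)
    if not (hill_slope > 0):
        raise InvalidInputError(f"hill_slope must be > 0, got {hill_slope}")
    _check_ph(midpoint_ph)
    lactone = 1.0 / (1.0 + 10.0 ** (hill_slope * (midpoint_ph - ph)))
    ionized = ionized_fraction(ph, props) if props is not None else float("nan")
    return SpeciationState(
        ph=ph,
        lactone_fraction=lactone,
        carboxylate_fraction=1.0 - lactone,
        ionized_fraction=ionized,
    )


def partition_coefficients(
    props: CompoundProperties,
    tissue_compositions: Mapping[str, Mapping[str, float]],
    tissue_binding_ratio: float = TISSUE_BINDING_RATIO,
) -> PartitionCoefficientSet:
    """Composition-based tissue:plasma Kp for every organ.

    A simplified tissue-homogenate model of the Poulin-Theil family:

        Kp_organ = fu_p * (f_water + D_vo * f_lipid) / fu_t

    where ``f_water``/``f_lipid`` are the fractional water and total-lipid
    content of the organ, ``D_vo`` is the neutral-oil (vegetable
    oil:water) distribution coefficient estimated from octanol lipophilicity
    by the standard regression ``log D_vo = 1.115 * log_p - 1.35``, and the
    tissue unbound fraction is estimated from the plasma one as

        fu_t = 1 / (1 + tissue_binding_ratio * (1 - fu_p) / fu_p).

    With the default ``tissue_binding_ratio = 0`` this reduces to
    ``Kp = fu_p * (f_water + D_vo * f_lipid)``: tissue affinity is carried
    by the lipid term alone and plasma protein binding by ``fu_p``.
    The same lipid affinity is applied uniformly to every organ (no
    adipose-specific solvent), which keeps the model a pure deterministic
    function of the tabulated compound parameters and the organ
    composition table. For an unbound compound against a 100%-water organ
    the formula reduces to Kp = 1 exactly.

    Parameters
    ----------
    tissue_compositions : mapping organ -> {"water_fraction": .., "lipid_fraction": ..}
        Must cover every organ for which a Kp is requested.
    """
    fu = props.fraction_unbound
    fu_t = 1.0 / (1.0 + tissue_binding_ratio * (1.0 - fu) / fu)
    dist_coeff = 10.0 ** (1.115 * props.log_p - 1.35)
    kp: dict[str, float] = {}
    for organ, comp in tissue_compositions.items():
        try:
            f_w = comp["water_fraction"]
            f_l = comp["lipid_fraction"]
        except KeyError as exc:
            raise ConfigurationError(
                f"composition table for organ {organ!r} lacks {exc}"
            ) from None
        if f_w + f_l > 1.0 + 1e-9:
            raise ConfigurationError(
                f"organ {organ!r}: water + lipid fractions exceed 1"
            )
        kp[organ] = fu * (f_w + dist_coeff * f_l) / fu_t
    return PartitionCoefficientSet(compound=props.name, kp=kp)
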