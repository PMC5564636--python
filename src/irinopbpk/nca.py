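"""Non-compartmental analysis of concentration-time profiles.

Computes the standard NCA parameter set — AUC to the last sample
(linear trapezoid), AUC extrapolated to infinity, Cmax/tmax, terminal
slope λz and half-life, mean residence time with infusion correction,
clearance and volumes of distribution — from either an observed sparse
dataset or a simulated profile. Working units follow the clinical
convention for this drug: concentrations in μmol/l, sampling times in
hours, AUC in μmol·min/l, clearance in ml/min/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .pbpk_engine import ConcentrationProfile, DoseRegimen

__all__ = [
    "ObservedDataset",
    "NCAResult",
    "auc_trapezoid",
    "cmax_tmax",
    "terminal_slope",
    "auc_extrapolate",
    "mrt",
    "run_nca",
    "InsufficientDataError",
    "InvalidSlopeError",
]

NA = float("nan")


class InsufficientDataError(ValueError):
    pass


class InvalidSlopeError(ValueError):
    pass


@dataclass(frozen=True)
class ObservedDataset:
    """Sparse per-species concentration-time observations.

    ``samples`` maps species → (times_h, concentrations_umol_l). Exact
    duplicate rows are dropped on construction; after deduplication times
    must be strictly increasing and concentrations non-negative.
    """

    samples: Mapping[str, tuple[np.ndarray, np.ndarray]]
    regimen: DoseRegimen | None = None

    def __post_init__(self) -> None:
        clean = {}
        for species, (t, c) in self.samples.items():
            t = np.asarray(t, dtype=float)
            c = np.asarray(c, dtype=float)
            if t.shape != c.shape or t.ndim != 1:
                raise InsufficientDataError(
                    f"{species}: times and concentrations must be equal-length 1-D"
                )
            keep = np.ones(len(t), dtype=bool)
            keep[1:] = (np.diff(t) != 0) | (np.diff(c) != 0)
            t, c = t[keep], c[keep]
            bad = np.where(np.diff(t) <= 0)[0]
            if len(bad):
                raise InsufficientDataError(
                    f"{species}: times not strictly increasing at rows {bad + 1}"
                )
            if np.any(c < 0):
                raise InsufficientDataError(f"{species}: negative concentrations")
            t.setflags(write=False)
            c.setflags(write=False)
            clean[species] = (t, c)
        object.__setattr__(self, "samples", clean)

    @property
    def species(self) -> list[str]:
        return list(self.samples)

    def get(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        return self.samples[species]


@dataclass(frozen=True)
class NCAResult:
    """Full NCA parameter set; unavailable entries are NaN.

    Units: AUCs μmol·min/l, concentrations μmol/l, times h, lambda_z 1/h,
    clearance ml/min/kg, volumes ml/kg.
    """

    species: str
    auc_tend: float
    auc_inf: float = NA
    pct_auc_extrapolated: float = NA
    cmax: float = NA
    tmax: float = NA
    c_tend: float = NA
    half_life: float = NA
    lambda_z: float = NA
    mrt: float = NA
    clearance: float = NA
    vd_plasma: float = NA
    vd_ss: float = NA

    def as_dict(self) -> dict[str, float]:
        return {
            "auc_tend": self.auc_tend, "auc_inf": self.auc_inf,
            "pct_auc_extrapolated": self.pct_auc_extrapolated,
            "cmax": self.cmax, "tmax": self.tmax, "c_tend": self.c_tend,
            "half_life": self.half_life, "lambda_z": self.lambda_z,
            "mrt": self.mrt, "clearance": self.clearance,
            "vd_plasma": self.vd_plasma, "vd_ss": self.vd_ss,
        }


def _extract(data, species: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, ObservedDataset):
        return data.get(species)
    if isinstance(data, ConcentrationProfile):
        return data.times_h, data.plasma[species]
    raise TypeError(f"cannot extract a profile from {type(data).__name__}")


def auc_trapezoid(data, species: str) -> float:
    """Linear trapezoidal AUC from first to last sample, in μmol·min/l."""
    t, c = _extract(data, species)
    if len(t) < 2:
        raise InsufficientDataError("AUC needs at least 2 points")
    return float(np.trapezoid(c, t)) * 60.0


def cmax_tmax(data, species: str) -> tuple[float, float]:
    """Maximum concentration and its time; ties broken by earliest time."""
    t, c = _extract(data, species)
    if len(t) < 1:
        raise InsufficientDataError("empty profile")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def terminal_slope(data, species: str,
                   n_terminal_points: int = 3,
                   selection: str = "fixed") -> tuple[float, float]:
    """Terminal elimination rate λz (1/h) and half-life (h).

    ``selection="fixed"`` regresses log concentration on time over the last
    ``n_terminal_points`` samples; ``selection="auto"`` picks the suffix of
    length ≥ ``n_terminal_points`` (excluding the Cmax point and earlier)
    that maximizes adjusted R².
    """
    t, c = _extract(data, species)
    pos = c > 0
    if selection == "fixed":
        if len(t) < n_terminal_points or n_terminal_points < 3:
            raise InsufficientDataError("need >= 3 terminal points")
        tt, cc = t[-n_terminal_points:], c[-n_terminal_points:]
        if np.any(cc <= 0):
            raise InsufficientDataError("non-positive terminal concentrations")
        lam = _loglinear_rate(tt, cc)
    elif selection == "auto":
        i_cmax = int(np.argmax(c))
        best, best_r2a = None, -np.inf
        for start in range(i_cmax + 1, len(t) - n_terminal_points + 1):
            tt, cc = t[start:], c[start:]
            if np.any(cc <= 0):
                continue
            lam_k, r2a = _loglinear_rate(tt, cc, adjusted_r2=True)
            if lam_k > 0 and r2a > best_r2a:
                best, best_r2a = lam_k, r2a
        if best is None:
            raise InsufficientDataError("no admissible terminal window")
        lam = best
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if lam <= 0:
        raise InvalidSlopeError(f"non-positive terminal slope {lam:.4g} 1/h")
    return float(lam), float(math.log(2) / lam)


def _loglinear_rate(t: np.ndarray, c: np.ndarray, adjusted_r2: bool = False):
    y = np.log(c)
    n = len(t)
    slope, intercept = np.polyfit(t, y, 1)
    if not adjusted_r2:
        return -slope
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2a = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return -slope, r2a


def auc_extrapolate(data, species: str, lambda_z: float) -> tuple[float, float]:
    """AUC to infinity and the extrapolated percentage.

    ``auc_inf = auc_tend + C_last / λz`` with the tail converted to
    μmol·min/l; the percentage is 100 × (auc_inf − auc_tend) / auc_inf.
    """
    if not (lambda_z > 0):
        raise InvalidSlopeError(f"lambda_z must be > 0, got {lambda_z}")
    t, c = _extract(data, species)
    auc_tend = auc_trapezoid(data, species)
    tail = c[-1] / lambda_z * 60.0
    auc_inf = auc_tend + tail
    pct = 100.0 * (auc_inf - auc_tend) / auc_inf if auc_inf > 0 else NA
    return float(auc_inf), float(pct)


def mrt(data, species: str, infusion_duration: float = 0.0,
        lambda_z: float | None = None,
        n_terminal_points: int = 3) -> float:
    """Mean residence time in hours.

    AUMC/AUC with mono-exponential tail extension beyond the last sample,
    minus ``infusion_duration``/2 (infusion duration given in minutes, the
    regimen's native unit).
    """
    t, c = _extract(data, species)
    if lambda_z is None:
        lambda_z, _ = terminal_slope(data, species, n_terminal_points)
    if not (lambda_z > 0):
        raise InvalidSlopeError("MRT requires a positive terminal slope")
    auc_h = float(np.trapezoid(c, t)) + c[-1] / lambda_z
    aumc_h = float(np.trapezoid(t * c, t)) \
        + c[-1] * t[-1] / lambda_z + c[-1] / lambda_z**2
    return float(aumc_h / auc_h - infusion_duration / 60.0 / 2.0)


def run_nca(
    data,
    species: str,
    regimen: DoseRegimen | None = None,
    body_weight: float | None = None,
    dose_umol: float | None = None,
    n_terminal_points: int = 3,
    terminal_selection: str = "fixed",
) -> NCAResult:
    """Assemble the full NCA parameter set for one species.

    Clearance and the volume terms need a dose in μmol and a body weight in
    kg; when either is missing (or ``data`` carries no dose context) those
    fields are NaN. A profile too sparse for a terminal fit yields NaN for
    every λz-derived field instead of raising.
    """
    t, c = _extract(data, species)
    if len(t) < 1:
        raise InsufficientDataError("empty profile")
    if regimen is None and isinstance(data, ObservedDataset):
        regimen = data.regimen
    if dose_umol is None and isinstance(data, ConcentrationProfile):
        # the profile's dose context refers to the administered compound;
        # dose-derived parameters for a formed metabolite stay NaN
        if regimen is None or regimen.compound == species:
            dose_umol = data.dose_umol

    cmax, tmax = cmax_tmax(data, species)
    result: dict[str, float] = {
        "cmax": cmax, "tmax": tmax, "c_tend": float(c[-1]),
        "auc_tend": NA, "auc_inf": NA, "pct_auc_extrapolated": NA,
        "half_life": NA, "lambda_z": NA, "mrt": NA,
        "clearance": NA, "vd_plasma": NA, "vd_ss": NA,
    }
    if len(t) >= 2:
        result["auc_tend"] = auc_trapezoid(data, species)
    tau_min = regimen.infusion_duration if regimen is not None else 0.0
    try:
        lam, t_half = terminal_slope(data, species, n_terminal_points,
                                     terminal_selection)
        result["lambda_z"], result["half_life"] = lam, t_half
        result["auc_inf"], result["pct_auc_extrapolated"] = \
            auc_extrapolate(data, species, lam)
        result["mrt"] = mrt(data, species, tau_min, lambda_z=lam)
    except (InsufficientDataError, InvalidSlopeError):
        pass

    if dose_umol is not None and body_weight is not None \
            and math.isfinite(result["auc_inf"]) and result["auc_inf"] > 0:
        cl_l_min = dose_umol / result["auc_inf"]          # L/min
        cl = cl_l_min * 1000.0 / body_weight              # ml/min/kg
        result["clearance"] = cl
        lam = result["lambda_z"]
        if lam > 0:
            result["vd_plasma"] = cl / (lam / 60.0)       # ml/kg
        if math.isfinite(result["mrt"]):
            result["vd_ss"] = cl * result["mrt"] * 60.0   # ml/kg
    return NCAResult(species=species, **result)
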