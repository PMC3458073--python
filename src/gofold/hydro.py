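"""Analytic hydrodynamic calculators.

Stokes radius from molecular mass uses the empirical globular-protein
power law log10(Rs[Å]) = −0.254 + 0.369·log10(MW[Da]).  Sedimentation
observables convert through the Svedberg relation
M = s0·R·T / (D0·(1 − v̄·ρ)) and the Stokes–Einstein relation
Rs = k_B·T / (6π·η·D0), in cgs units with results reported in Da and nm.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger("gofold")

RS_INTERCEPT = -0.254       # log10 Å
RS_SLOPE = 0.369
R_GAS_CGS = 8.314462618e7   # erg mol⁻¹ K⁻¹
KB_CGS = 1.380649e-16       # erg K⁻¹
SVEDBERG = 1e-13            # s


@dataclasses.dataclass
class HydroParams:
    """Inputs for the sedimentation conversions (cgs-flavoured units)."""

    mw: float | None = None      # Da
    s0: float | None = None      # Svedberg (10⁻¹³ s)
    d0: float | None = None      # cm² s⁻¹
    vbar: float = 0.73           # mL g⁻¹, partial specific volume
    rho: float = 1.0             # g mL⁻¹, solvent density
    eta: float = 0.01002         # poise, water at 20 °C
    temperature_K: float = 293.15

    def __post_init__(self) -> None:
        for name in ("mw", "s0", "d0", "vbar", "rho", "eta",
                     "temperature_K"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


def rs_from_mw(mw: float) -> float:
    """Predicted Stokes radius (nm) of a globular protein of mass mw (Da)."""
    mw = np.asarray(mw, float)
    if np.any(mw <= 0):
        raise ValueError("molecular mass must be positive")
    rs_angstrom = 10.0 ** (RS_INTERCEPT + RS_SLOPE * np.log10(mw))
    return rs_angstrom / 10.0 if np.ndim(mw) else float(rs_angstrom / 10.0)


def polydispersity_percent(rs_values, weights) -> float:
    """%Pd: mass-weighted SD of the size distribution over its mean, ×100."""
    rs = np.asarray(rs_values, float)
    w = np.asarray(weights, float)
    if rs.shape != w.shape or rs.size == 0:
        raise ValueError("rs_values and weights must be equal-length")
    if np.any(w < 0):
        raise ValueError("mass fractions must be non-negative")
    total = w.sum()
    if abs(total - 1.0) > 1e-6:
        logger.warning("mass fractions sum to %.6g; renormalizing", total)
    w = w / total
    mean = np.sum(w * rs)
    sd = np.sqrt(np.sum(w * (rs - mean) ** 2))
    return float(100.0 * sd / mean)


def svedberg_mass(p: HydroParams) -> float:
    """Molecular mass (Da) from s0 and D0 via the Svedberg equation."""
    if p.s0 is None or p.d0 is None:
        raise ValueError("svedberg_mass needs s0 and d0")
    buoyancy = 1.0 - p.vbar * p.rho
    if buoyancy <= 0:
        raise ValueError(
            f"vbar*rho = {p.vbar * p.rho:.4g} >= 1: buoyancy vanishes")
    return float(p.s0 * SVEDBERG * R_GAS_CGS * p.temperature_K
                 / (p.d0 * buoyancy))


def stokes_einstein_rs(p: HydroParams) -> float:
    """Stokes radius (nm) from D0 via the Stokes–Einstein equation."""
    if p.d0 is None:
        raise ValueError("stokes_einstein_rs needs d0")
    rs_cm = KB_CGS * p.temperature_K / (6.0 * np.pi * p.eta * p.d0)
    return float(rs_cm * 1e7)
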