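"""Two-state equilibrium unfolding: chemical and thermal fits.

Chemical denaturation follows the Santoro–Bolen linear-extrapolation
model: the free energy of unfolding is linear in denaturant,
ΔG(x) = ΔG° − m·x, and the observed signal is the population-weighted sum
of linearly sloped native and unfolded baselines.

Thermal denaturation uses the Gibbs–Helmholtz expression

    ΔG(T) = ΔH·(1 − T/Tm) − ΔCp·[(Tm − T) + T·ln(T/Tm)]

with ΔH the unfolding enthalpy at Tm and ΔCp the unfolding heat-capacity
change, again with linear pre- and post-transition baselines.

All fitting is internal to Kelvin; °C appears only at the interface.
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger("gofold")

R_KCAL = 1.9872e-3     # kcal mol⁻¹ K⁻¹
CELSIUS = 273.15
DEFAULT_FIT_T = 293.15  # K; isothermal experiments at 20 °C


class NoTransitionError(ValueError):
    """The data show no detectable two-state transition."""


@dataclasses.dataclass
class ChemicalFit:
    """Santoro–Bolen two-state parameters for one denaturation curve."""

    dG0: float                 # kcal/mol, water value
    m: float                   # kcal/mol/M
    s0_n: float                # native-baseline intercept (signal units)
    s0_u: float                # unfolded-baseline intercept
    slope_n: float = 0.0       # signal per M
    slope_u: float = 0.0
    temperature_K: float = DEFAULT_FIT_T
    m_fixed: bool = False
    rss: float = np.nan        # residual sum of squares at the optimum
    n_points: int = 0
    cov: np.ndarray | None = None   # covariance of the free parameters

    @property
    def cm(self) -> float:
        """Transition midpoint Cm = ΔG°/m (M); exact by construction."""
        return self.dG0 / self.m


@dataclasses.dataclass
class ThermalFit:
    """Two-state thermal unfolding parameters."""

    dH: float                  # kcal/mol at Tm
    tm_K: float
    dCp: float                 # kcal/mol/K
    s0_n: float
    s0_u: float
    l_n: float = 0.0           # baseline slopes, signal per K
    l_u: float = 0.0
    dcp_fixed: bool = False
    rss: float = np.nan
    n_points: int = 0
    cov: np.ndarray | None = None

    @property
    def tm_C(self) -> float:
        return self.tm_K - CELSIUS


@dataclasses.dataclass
class StabilityCurve:
    """ΔG(T) evaluated on a dense grid, with its interior maximum."""

    temps_K: np.ndarray
    dG: np.ndarray
    dG_max: float | None
    t_at_max_K: float | None

    @property
    def t_at_max_C(self) -> float | None:
        return None if self.t_at_max_K is None else self.t_at_max_K - CELSIUS


# ---------------------------------------------------------------------------
# Signal models
# ---------------------------------------------------------------------------

def chem_signal(x, params: ChemicalFit):
    """Observed signal at denaturant concentration x (M)."""
    x = np.asarray(x, float)
    rt = R_KCAL * params.temperature_K
    k = np.exp(-(params.dG0 - params.m * x) / rt)
    s_n = params.s0_n + params.slope_n * x
    s_u = params.s0_u + params.slope_u * x
    return (s_n + s_u * k) / (1.0 + k)


def gibbs_helmholtz(dH: float, tm_K: float, dCp: float, T):
    """ΔG of unfolding (kcal/mol) at temperature T (K)."""
    T = np.asarray(T, float)
    if np.any(T <= 0) or tm_K <= 0:
        raise ValueError("temperatures must be positive (Kelvin)")
    return (dH * (1.0 - T / tm_K)
            - dCp * ((tm_K - T) + T * np.log(T / tm_K)))


def thermal_signal(T, params: ThermalFit):
    """Observed signal at temperature T (K); baselines are linear in Kelvin."""
    T = np.asarray(T, float)
    dg = gibbs_helmholtz(params.dH, params.tm_K, params.dCp, T)
    k = np.exp(-dg / (R_KCAL * T))
    f_u = k / (1.0 + k)
    s_n = params.s0_n + params.l_n * T
    s_u = params.s0_u + params.l_u * T
    return s_n * (1.0 - f_u) + s_u * f_u


# ---------------------------------------------------------------------------
# Shared fitting helpers
# ---------------------------------------------------------------------------

def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        arr = data.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("data must be a 2-column (x, signal) table")
    order = np.argsort(arr[:, 0])
    return arr[order, 0], arr[order, 1]


def _transition_guess(x: np.ndarray, y: np.ndarray) -> float:
    """Mid-crossing of the apparent unfolded fraction; raises if absent.

    Baselines are estimated from the outer 20 % of points on each side;
    a transition is required to sweep most of the span between them.
    """
    k = max(2, len(x) // 5)
    lo, hi = y[:k], y[-k:]
    amp = abs(hi.mean() - lo.mean())
    # noise from detrended ends; a sloped straight line contributes none
    noise = max(np.std(lo - np.polyval(np.polyfit(x[:k], lo, 1), x[:k])),
                np.std(hi - np.polyval(np.polyfit(x[-k:], hi, 1), x[-k:])),
                1e-12)
    if amp < 5.0 * noise:
        raise NoTransitionError(
            "no transition detectable: signal change is within baseline noise")
    # a single straight line through everything is a baseline, not a melt
    line_resid = y - np.polyval(np.polyfit(x, y, 1), x)
    if np.std(line_resid) < 0.01 * np.ptp(y):
        raise NoTransitionError(
            "no transition detectable: data are consistent with one "
            "straight baseline")
    f = (y - lo.mean()) / (hi.mean() - lo.mean())
    crossing = np.flatnonzero(np.diff(np.sign(f - 0.5)))
    if crossing.size == 0:
        raise NoTransitionError("signal never crosses the transition midpoint")
    i = int(crossing[0])
    # linear interpolation between the bracketing grid points
    f0, f1 = f[i], f[i + 1]
    return float(x[i] + (0.5 - f0) / (f1 - f0) * (x[i + 1] - x[i]))


def _solve(residual_fn, p0: np.ndarray):
    sol = least_squares(residual_fn, p0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(
            f"fit did not converge: {sol.message}; check that the data span "
            "the transition and the fixed parameters are sensible")
    jtj = sol.jac.T @ sol.jac
    dof = max(len(sol.fun) - len(p0), 1)
    try:
        cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
    except np.linalg.LinAlgError:
        raise RuntimeError(
            "singular fit: parameters are not identifiable from these data; "
            "try fixing m or dCp, or extend the baselines")
    return sol, cov


# ---------------------------------------------------------------------------
# Chemical fit
# ---------------------------------------------------------------------------

def fit_chemical(data, m_mode: float | str = "free",
                 temperature_K: float = DEFAULT_FIT_T) -> ChemicalFit:
    """Nonlinear least-squares Santoro–Bolen fit of an (x, signal) table.

    ``m_mode`` is either the string "free" or a numeric m-value to hold
    fixed (the experimental practice here: m from an empirical
    surface-area correlation rather than floated).  Baseline slopes are
    fitted but initialized at zero.  Deterministic given the data.
    """
    x, y = _as_xy(data)
    if len(x) < 6:
        raise ValueError("need at least 6 points spanning the transition")
    cm0 = _transition_guess(x, y)
    k = max(2, len(x) // 5)
    s0n0, s0u0 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
    fixed_m = None if m_mode == "free" else float(m_mode)
    m0 = fixed_m if fixed_m is not None else 2.0
    dg0_0 = m0 * cm0

    def unpack(p):
        if fixed_m is None:
            dg0, m, s0n, s0u, an, au = p
        else:
            dg0, s0n, s0u, an, au = p
            m = fixed_m
        return ChemicalFit(dG0=dg0, m=m, s0_n=s0n, s0_u=s0u,
                           slope_n=an, slope_u=au,
                           temperature_K=temperature_K)

    def residual(p):
        return chem_signal(x, unpack(p)) - y

    p0 = ([dg0_0, m0, s0n0, s0u0, 0.0, 0.0] if fixed_m is None
          else [dg0_0, s0n0, s0u0, 0.0, 0.0])
    sol, cov = _solve(residual, np.asarray(p0, float))
    fit = unpack(sol.x)
    fit.m_fixed = fixed_m is not None
    fit.rss = float(2.0 * sol.cost)
    fit.n_points = len(x)
    fit.cov = cov
    return fit


# ---------------------------------------------------------------------------
# Thermal fit
# ---------------------------------------------------------------------------

def fit_thermal(data, dcp_mode: float | str = "free",
                celsius: bool | None = None) -> ThermalFit:
    """Two-state Gibbs–Helmholtz fit of a (T, signal) melting curve.

    ``dcp_mode`` is "free" or a numeric ΔCp (kcal/mol/K) to hold fixed.
    Temperatures below 150 are interpreted as °C unless ``celsius`` says
    otherwise; fitting is internal to Kelvin.
    """
    t, y = _as_xy(data)
    if len(t) < 8:
        raise ValueError("need at least 8 points with baseline coverage")
    if celsius is None:
        celsius = bool(np.max(t) < 150.0)
    t_K = t + CELSIUS if celsius else t
    tm0 = _transition_guess(t_K, y)
    k = max(2, len(t_K) // 5)
    # baseline intercept/slope guesses from the outer points
    an = np.polyfit(t_K[:k], y[:k], 1)
    au = np.polyfit(t_K[-k:], y[-k:], 1)
    # logistic pre-fit for the enthalpy: d f_U/dT at Tm is dH/(4 R Tm²)
    f = (y - np.polyval(an, t_K)) / (np.polyval(au, t_K) - np.polyval(an, t_K))
    df = np.gradient(np.clip(f, 0.0, 1.0), t_K)
    slope = float(np.max(df)) if np.max(df) > 0 else 0.01
    dh0 = min(max(4.0 * R_KCAL * tm0 ** 2 * slope, 10.0), 300.0)
    fixed_dcp = None if dcp_mode == "free" else float(dcp_mode)
    dcp0 = fixed_dcp if fixed_dcp is not None else 1.0

    def unpack(p):
        if fixed_dcp is None:
            dh, tm, dcp, s0n, s0u, ln, lu = p
        else:
            dh, tm, s0n, s0u, ln, lu = p
            dcp = fixed_dcp
        return ThermalFit(dH=dh, tm_K=tm, dCp=dcp, s0_n=s0n, s0_u=s0u,
                          l_n=ln, l_u=lu)

    def residual(p):
        return thermal_signal(t_K, unpack(p)) - y

    p0 = ([dh0, tm0, dcp0, an[1], au[1], an[0], au[0]] if fixed_dcp is None
          else [dh0, tm0, an[1], au[1], an[0], au[0]])
    sol, cov = _solve(residual, np.asarray(p0, float))
    fit = unpack(sol.x)
    fit.dcp_fixed = fixed_dcp is not None
    fit.rss = float(2.0 * sol.cost)
    fit.n_points = len(t_K)
    fit.cov = cov
    return fit


def stability_curve(params: ThermalFit,
                    t_range_K: tuple[float, float] = (253.15, 393.15),
                    step_K: float = 0.1) -> StabilityCurve:
    """ΔG(T) on a dense grid with its interior maximum.

    With ΔCp > 0 the curve has a unique maximum at ln(Tm/T*) = ΔH/(Tm·ΔCp);
    the grid maximum matches that closed form to one grid step.  With
    ΔCp <= 0 no interior maximum exists and None is reported.
    """
    temps = np.arange(t_range_K[0], t_range_K[1] + step_K / 2, step_K)
    dg = gibbs_helmholtz(params.dH, params.tm_K, params.dCp, temps)
    if params.dCp <= 0:
        logger.warning("dCp <= 0: stability curve has no interior maximum")
        return StabilityCurve(temps_K=temps, dG=dg, dG_max=None,
                              t_at_max_K=None)
    i = int(np.argmax(dg))
    return StabilityCurve(temps_K=temps, dG=dg, dG_max=float(dg[i]),
                          t_at_max_K=float(temps[i]))
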