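"""Multiple-histogram (WHAM) thermodynamics over (E, Q) samples.

Constant-temperature runs are pooled into a shared two-dimensional
histogram over potential energy E and fraction of native contacts Q.  The
self-consistent WHAM equations yield a consensus density of states
Ω(E, Q), from which any-temperature averages follow by Boltzmann
reweighting: the heat capacity Cv(T) = (⟨E²⟩−⟨E⟩²)/T², the melting
temperature as the Cv peak, and free-energy profiles
F(Q|T) = −T·ln P(Q|T).

Reduced units throughout (k_B = 1, energies in ε).  The iteration is on a
log scale (log-sum-exp) for numerical robustness; each bin's energy is
represented by the pooled within-bin sample mean, which removes most of
the discretization bias of plain bin centers.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.special import logsumexp

from .simulate import Trajectory

logger = logging.getLogger("gofold")

DEFAULT_E_BINS = 60
MAX_Q_BINS = 50
EXTRAPOLATION_GUARD = 0.20   # allowed fraction beyond the simulated bracket


class WhamConvergenceError(RuntimeError):
    def __init__(self, residual_history):
        self.residual_history = residual_history
        super().__init__(
            f"WHAM did not converge; final residual "
            f"{residual_history[-1]:.3e} after {len(residual_history)} "
            "iterations")


@dataclasses.dataclass
class WhamResult:
    """Consensus density of states on the shared (E, Q) grid."""

    e_edges: np.ndarray        # (nE+1,)
    q_edges: np.ndarray        # (nQ+1,)
    e_rep: np.ndarray          # (nE, nQ) representative energy per bin
    log_omega: np.ndarray      # (nE, nQ), -inf where never sampled
    f_shifts: np.ndarray       # per-run dimensionless free-energy shifts
    temperatures: np.ndarray   # per-run
    counts: np.ndarray | None = None   # pooled sample counts per bin
    n_iterations: int = 0
    final_residual: float = np.nan

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    def log_weights(self, T: float) -> np.ndarray:
        """Normalized log Boltzmann weights per bin at temperature T."""
        lw = self.log_omega - self.e_rep / T
        return lw - logsumexp(lw[np.isfinite(lw)])


@dataclasses.dataclass
class ThermoCurves:
    temps: np.ndarray
    cv: np.ndarray
    tm: float


def _normalize_runs(runs) -> list[tuple[float, np.ndarray, np.ndarray | None]]:
    out = []
    for run in runs:
        if isinstance(run, Trajectory):
            out.append((run.config.temperature, run.energies, run.q_values))
        else:
            t, e = run[0], np.asarray(run[1], float)
            q = np.asarray(run[2], float) if len(run) > 2 and run[2] is not None else None
            out.append((float(t), e, q))
    return out


def runs_from_trajectories(trajectories: list[Trajectory],
                           discard_first: float = 0.5):
    """(T, E, Q) triples from the equilibrated part of each trajectory."""
    out = []
    for tr in trajectories:
        start = int(np.floor(tr.n_frames * discard_first))
        out.append((tr.config.temperature, tr.energies[start:],
                    tr.q_values[start:]))
    return out


def _overlap_check(runs) -> None:
    order = np.argsort([t for t, _, _ in runs])
    for a, b in zip(order[:-1], order[1:]):
        ea, eb = runs[a][1], runs[b][1]
        lo, hi = max(ea.min(), eb.min()), min(ea.max(), eb.max())
        frac = min(np.mean((ea >= lo) & (ea <= hi)),
                   np.mean((eb >= lo) & (eb <= hi)))
        if frac < 0.01:
            logger.warning(
                "energy histograms at T=%.4g and T=%.4g overlap by %.2f%%; "
                "WHAM bridging will be poor", runs[a][0], runs[b][0],
                100 * frac)


def wham_solve(runs, tol: float = 1e-7, max_iter: int = 100_000,
               n_e_bins: int = DEFAULT_E_BINS,
               n_q_bins: int | None = None) -> WhamResult:
    """Solve the WHAM equations for a set of constant-temperature runs.

    ``runs`` is a list of Trajectory objects or (temperature, energies, q)
    tuples (q may be None, collapsing the Q axis).  Deterministic given
    the inputs; run order does not matter.  Convergence is measured as
    the largest change in any per-run shift between iterations.
    """
    runs = _normalize_runs(runs)
    if not runs:
        raise ValueError("need at least one run")
    if len(runs) > 1:
        _overlap_check(runs)

    all_e = np.concatenate([e for _, e, _ in runs])
    has_q = runs[0][2] is not None
    e_lo, e_hi = float(all_e.min()), float(all_e.max())
    pad = max(1e-9, 1e-9 * abs(e_hi))
    e_edges = np.linspace(e_lo, e_hi + pad, n_e_bins + 1)
    if has_q:
        nq = n_q_bins or MAX_Q_BINS
        q_edges = np.linspace(0.0, 1.0 + 1e-12, nq + 1)
    else:
        q_edges = np.array([0.0, 1.0 + 1e-12])

    n_runs = len(runs)
    shape = (n_e_bins, len(q_edges) - 1)
    counts = np.zeros((n_runs,) + shape)
    e_sum = np.zeros(shape)
    for k, (_, e, q) in enumerate(runs):
        qv = q if has_q else np.zeros_like(e)
        h, _, _ = np.histogram2d(e, qv, bins=[e_edges, q_edges])
        counts[k] = h
        ei = np.clip(np.digitize(e, e_edges) - 1, 0, n_e_bins - 1)
        qi = np.clip(np.digitize(qv, q_edges) - 1, 0, shape[1] - 1)
        np.add.at(e_sum, (ei, qi), e)
    total = counts.sum(axis=0)
    centers = 0.5 * (e_edges[:-1] + e_edges[1:])
    e_rep = np.where(total > 0, e_sum / np.maximum(total, 1),
                     centers[:, None] * np.ones(shape))

    temps = np.array([t for t, _, _ in runs])
    n_k = counts.sum(axis=(1, 2))
    occupied = total > 0
    log_total = np.where(occupied, np.log(np.maximum(total, 1)), -np.inf)

    f = np.zeros(n_runs)
    residuals = []
    # beta_k * E_b for every run and bin, computed once
    be = e_rep[None, :, :] / temps[:, None, None]
    log_nk = np.log(n_k)[:, None, None]
    for it in range(max_iter):
        denom = logsumexp(log_nk + f[:, None, None] - be, axis=0)
        log_omega = np.where(occupied, log_total - denom, -np.inf)
        flat = log_omega[occupied]
        f_new = np.array([-logsumexp(flat - (e_rep[occupied] / t))
                          for t in temps])
        f_new -= f_new[0]
        res = float(np.max(np.abs(f_new - f)))
        residuals.append(res)
        f = f_new
        if res < tol:
            denom = logsumexp(log_nk + f[:, None, None] - be, axis=0)
            log_omega = np.where(occupied, log_total - denom, -np.inf)
            # anchor the arbitrary additive constant for determinism
            log_omega -= logsumexp(log_omega[occupied])
            return WhamResult(
                e_edges=e_edges, q_edges=q_edges, e_rep=e_rep,
                log_omega=log_omega, f_shifts=f, temperatures=temps,
                counts=total, n_iterations=it + 1, final_residual=res)
    raise WhamConvergenceError(residuals)


# ---------------------------------------------------------------------------
# Reweighted observables
# ---------------------------------------------------------------------------

def _check_bracket(result: WhamResult, temps: np.ndarray) -> None:
    t_lo, t_hi = result.temperatures.min(), result.temperatures.max()
    span = t_hi - t_lo if t_hi > t_lo else t_hi
    lo = t_lo - EXTRAPOLATION_GUARD * span
    hi = t_hi + EXTRAPOLATION_GUARD * span
    if np.any(temps < lo) or np.any(temps > hi):
        raise ValueError(
            f"requested temperatures extrapolate beyond the guard "
            f"[{lo:.4g}, {hi:.4g}] around the simulated bracket "
            f"[{t_lo:.4g}, {t_hi:.4g}]")


def mean_energy(result: WhamResult, T: float) -> float:
    lw = result.log_weights(T)
    ok = np.isfinite(lw)
    w = np.exp(lw[ok])
    return float(np.sum(w * result.e_rep[ok]))


def heat_capacity(result: WhamResult, temps: np.ndarray | None = None,
                  n_grid: int = 2001) -> ThermoCurves:
    """Cv(T) from reweighted energy moments; Tm is the Cv peak.

    With no explicit grid, a 2001-point grid across the simulated
    temperature bracket is used; argmax ties break toward the lowest T.
    """
    if temps is None:
        temps = np.linspace(result.temperatures.min(),
                            result.temperatures.max(), n_grid)
    temps = np.asarray(temps, float)
    _check_bracket(result, temps)
    cv = np.empty_like(temps)
    for i, t in enumerate(temps):
        lw = result.log_weights(t)
        ok = np.isfinite(lw)
        w = np.exp(lw[ok])
        e = result.e_rep[ok]
        e1 = np.sum(w * e)
        e2 = np.sum(w * e * e)
        cv[i] = max(e2 - e1 * e1, 0.0) / (t * t)
    tm = float(temps[int(np.argmax(cv))])
    return ThermoCurves(temps=temps, cv=cv, tm=tm)


def free_energy_profile(result: WhamResult, T: float,
                        min_count: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """F(Q) = −T·ln P(Q|T) with the minimum shifted to zero.

    Returns (bin centers, F).  Q bins never sampled, or backed by fewer
    than ``min_count`` pooled samples (where a reweighted probability is
    dominated by shot noise), are NaN; empty bins strictly inside the
    sampled envelope are reported NaN with a warning, since they make the
    profile unreliable there.
    """
    _check_bracket(result, np.asarray([T]))
    lw = result.log_weights(T)
    with np.errstate(over="ignore"):
        p_q = np.exp(logsumexp(np.where(np.isfinite(lw), lw, -np.inf),
                               axis=0))
    if result.counts is not None:
        p_q = np.where(result.counts.sum(axis=0) >= min_count, p_q, 0.0)
    occ = np.flatnonzero(p_q > 0)
    f = np.full_like(p_q, np.nan)
    f[occ] = -T * np.log(p_q[occ])
    if occ.size:
        inner = np.arange(occ.min(), occ.max() + 1)
        holes = np.setdiff1d(inner, occ)
        if holes.size:
            logger.warning("%d empty Q bins inside the sampled envelope",
                           holes.size)
        f -= np.nanmin(f)
    return result.q_centers, f


def coexistence_temperature(result: WhamResult, n_grid: int = 201,
                            min_prominence: float = 0.1,
                            min_separation: float = 0.3) -> float | None:
    """Temperature where the folded and unfolded basins of F(Q) balance.

    The melting temperature of a two-state folder is the coexistence
    point: F(Q) shows two basins of equal depth.  For finite systems the
    Cv peak and the coexistence point can differ slightly, and barrier
    heights are only well defined near coexistence, so profile analyses
    use this estimate.  Scans a temperature grid across the simulated
    bracket and returns the temperature minimizing the depth difference
    between the outermost pair of basins.  Only basin pairs at least
    ``min_separation`` apart in Q qualify — adjacent sampling dimples on
    one shoulder are not a folded/unfolded pair.  None if no scanned
    temperature shows such a pair.
    """
    temps = np.linspace(result.temperatures.min(),
                        result.temperatures.max(), n_grid)
    best_t, best_gap = None, np.inf
    for t in temps:
        q, f = free_energy_profile(result, t)
        ok = np.isfinite(f)
        qv, fv = q[ok], f[ok]
        basins = _basin_indices(fv, min_prominence)
        if len(basins) < 2:
            continue
        if qv[basins[-1]] - qv[basins[0]] < min_separation:
            continue
        gap = abs(fv[basins[0]] - fv[basins[-1]])
        if gap < best_gap:
            best_t, best_gap = float(t), gap
    if best_t is None:
        logger.warning("no scanned temperature shows two separated "
                       "F(Q) basins")
    return best_t


def _basin_indices(f: np.ndarray, min_prominence: float) -> np.ndarray:
    from scipy.signal import find_peaks

    if len(f) < 3:
        return np.array([], dtype=int)
    pad = 10.0 * min_prominence + float(np.ptp(f))
    padded = np.concatenate([[-f[0] - pad], -f, [-f[-1] - pad]])
    minima, _ = find_peaks(padded, prominence=min_prominence)
    return minima - 1


def barrier_height(q_centers: np.ndarray, f_curve: np.ndarray, T: float,
                   min_prominence: float = 0.1) -> float | None:
    """ΔF‡ between the unfolded basin and the saddle, in units of kT.

    Basins are located as local minima of F(Q) with at least
    ``min_prominence`` (in ε) of surrounding relief, which keeps
    bin-to-bin sampling noise from being read as a basin.  The saddle is
    the maximum between the outermost pair of basins and the barrier is
    measured from the lower-Q (unfolded) basin.  With fewer than two
    basins the barrier is undefined and None is returned.
    """
    ok = np.isfinite(f_curve)
    q, f = q_centers[ok], f_curve[ok]
    if len(f) < 3:
        logger.warning("profile too short to locate a barrier")
        return None
    minima = _basin_indices(f, min_prominence)
    if len(minima) < 2:
        logger.warning("only one free-energy basin: barrier undefined")
        return None
    lo, hi = int(minima[0]), int(minima[-1])
    saddle = lo + int(np.argmax(f[lo:hi + 1]))
    return float((f[saddle] - f[lo]) / T)
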