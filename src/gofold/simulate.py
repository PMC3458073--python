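"""Energy, forces and Langevin dynamics for the Cα Gō model.

The potential is the standard Cα structure-based form: harmonic bonds and
angles, 1- and 3-fold cosine dihedrals, a 10–12 Lennard-Jones well for each
native contact (depth ε, minimum at the native distance), and an r⁻¹²
excluded-volume repulsion for every non-native pair with sequence
separation >= 4:

    V = Σ K_r (r − r0)²  +  Σ K_θ (θ − θ0)²
      + Σ [K_Φ1 (1 − cos(Φ − Φ0)) + K_Φ3 (1 − cos 3(Φ − Φ0))]
      + Σ_native ε [5 (r0/r)¹² − 6 (r0/r)¹⁰]
      + Σ_nonnative ε (σ0/r)¹²

Dynamics are integrated with the BAOAB Langevin splitting in reduced
units (k_B = 1, masses 1, energies in ε, time in τ).  Kernels are
numba-compiled; random numbers are drawn from a seeded numpy PCG64
generator outside the kernels so trajectories are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numba
import numpy as np
import pandas as pd

from .structure import GoTopology

logger = logging.getLogger("gofold")

DEFAULT_GAMMA = 1.2  # contact-formation threshold multiplier on r0


@dataclasses.dataclass
class SimulationConfig:
    """Constant-temperature run settings (reduced units)."""

    temperature: float           # ε / k_B
    n_steps: int
    timestep: float = 0.0005     # τ
    friction: float = 1.0        # τ⁻¹
    save_every: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (self.n_steps >= self.save_every >= 1):
            raise ValueError("need n_steps >= save_every >= 1")


@dataclasses.dataclass
class Trajectory:
    """Saved frames of one constant-temperature run."""

    frames: np.ndarray        # (F, n, 3) Å
    energies: np.ndarray      # (F,) potential energy, ε
    q_values: np.ndarray      # (F,) fraction of native contacts
    kinetic: np.ndarray       # (F,) kinetic energy, ε
    config: SimulationConfig
    topology: GoTopology

    @property
    def n_frames(self) -> int:
        return len(self.energies)

    @property
    def steps(self) -> np.ndarray:
        s = self.config.save_every
        return np.arange(1, self.n_frames + 1) * s


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _energy_forces(x, bond_r0, angle_theta0, dihedral_phi0, dihedral_w,
                   contacts, contact_r0, nonnative, k_r, k_theta,
                   k_phi1, k_phi3, eps, sigma):  # pragma: no cover - jit
    n = x.shape[0]
    f = np.zeros((n, 3))
    v = 0.0

    # bonds
    for i in range(n - 1):
        dx = x[i + 1] - x[i]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        dr = r - bond_r0[i]
        v += k_r * dr * dr
        coef = 2.0 * k_r * dr / r
        for d in range(3):
            f[i, d] += coef * dx[d]
            f[i + 1, d] -= coef * dx[d]

    # angles
    for a in range(1, n - 1):
        u = x[a - 1] - x[a]
        w = x[a + 1] - x[a]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nw = np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
        c = (u[0] * w[0] + u[1] * w[1] + u[2] * w[2]) / (nu * nw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - angle_theta0[a - 1]
        v += k_theta * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dvdth = 2.0 * k_theta * dth
        for d in range(3):
            dth_du = -(w[d] / (nu * nw) - c * u[d] / (nu * nu)) / s
            dth_dw = -(u[d] / (nu * nw) - c * w[d] / (nw * nw)) / s
            f[a - 1, d] -= dvdth * dth_du
            f[a + 1, d] -= dvdth * dth_dw
            f[a, d] += dvdth * (dth_du + dth_dw)

    # dihedrals
    for a in range(1, n - 2):
        w = dihedral_w[a - 1]
        if w == 0.0:
            continue
        b1 = x[a] - x[a - 1]
        b2 = x[a + 1] - x[a]
        b3 = x[a + 2] - x[a + 1]
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        xx = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        cr0 = n1[1] * n2[2] - n1[2] * n2[1]
        cr1 = n1[2] * n2[0] - n1[0] * n2[2]
        cr2 = n1[0] * n2[1] - n1[1] * n2[0]
        yy = (cr0 * b2[0] + cr1 * b2[1] + cr2 * b2[2]) / nb2
        phi = np.arctan2(yy, xx)
        dphi = phi - dihedral_phi0[a - 1]
        v += w * (k_phi1 * (1.0 - np.cos(dphi))
                  + k_phi3 * (1.0 - np.cos(3.0 * dphi)))
        dvdphi = w * (k_phi1 * np.sin(dphi)
                      + 3.0 * k_phi3 * np.sin(3.0 * dphi))
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        t12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        t32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for d in range(3):
            dphi_d0 = -nb2 / n1sq * n1[d]
            dphi_d3 = nb2 / n2sq * n2[d]
            dphi_d1 = -(1.0 + t12) * dphi_d0 + t32 * dphi_d3
            dphi_d2 = t12 * dphi_d0 - (1.0 + t32) * dphi_d3
            f[a - 1, d] -= dvdphi * dphi_d0
            f[a, d] -= dvdphi * dphi_d1
            f[a + 1, d] -= dvdphi * dphi_d2
            f[a + 2, d] -= dvdphi * dphi_d3

    # native contacts: 10-12 well with minimum -eps at r0
    for k in range(contacts.shape[0]):
        i = contacts[k, 0]
        j = contacts[k, 1]
        dx = x[j] - x[i]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r < 1e-6:
            raise ValueError("overlapping beads in native pair")
        q = contact_r0[k] / r
        q10 = q ** 10
        q12 = q10 * q * q
        v += eps * (5.0 * q12 - 6.0 * q10)
        dvdr = -60.0 * eps * (q12 - q10) / r
        coef = dvdr / r
        for d in range(3):
            f[i, d] += coef * dx[d]
            f[j, d] -= coef * dx[d]

    # non-native excluded volume
    for k in range(nonnative.shape[0]):
        i = nonnative[k, 0]
        j = nonnative[k, 1]
        dx = x[j] - x[i]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r < 1e-6:
            raise ValueError("overlapping beads in non-native pair")
        q12 = (sigma / r) ** 12
        v += eps * q12
        dvdr = -12.0 * eps * q12 / r
        coef = dvdr / r
        for d in range(3):
            f[i, d] += coef * dx[d]
            f[j, d] -= coef * dx[d]

    return v, f


@numba.njit(cache=True)
def _baoab_chunk(x, vel, f, normals, dt, c1, c2,
                 bond_r0, angle_theta0, dihedral_phi0, dihedral_w, contacts,
                 contact_r0, nonnative, k_r, k_theta, k_phi1, k_phi3, eps,
                 sigma):  # pragma: no cover - jit
    nsteps = normals.shape[0]
    v_pot = 0.0
    for s in range(nsteps):
        vel += 0.5 * dt * f
        x += 0.5 * dt * vel
        vel = c1 * vel + c2 * normals[s]
        x += 0.5 * dt * vel
        v_pot, f = _energy_forces(
            x, bond_r0, angle_theta0, dihedral_phi0, dihedral_w, contacts,
            contact_r0, nonnative, k_r, k_theta, k_phi1, k_phi3, eps, sigma)
        vel += 0.5 * dt * f
    return x, vel, f, v_pot


def _kernel_args(topology: GoTopology):
    contacts = topology.contacts.reshape(-1, 2).astype(np.int64)
    weight = (topology.dihedral_weight if topology.dihedral_weight
              is not None else np.ones_like(topology.dihedral_phi0))
    return (topology.bond_r0, topology.angle_theta0, topology.dihedral_phi0,
            np.asarray(weight, float), contacts, topology.contact_r0,
            topology.nonnative_pairs().reshape(-1, 2).astype(np.int64),
            topology.k_r, topology.k_theta, topology.k_phi1,
            topology.k_phi3, topology.epsilon, topology.sigma_nonnative)


# ---------------------------------------------------------------------------
# Public energy / force / observable API
# ---------------------------------------------------------------------------

def potential_energy(topology: GoTopology, coords: np.ndarray) -> float:
    """Evaluate the Gō potential (ε) for one conformation."""
    coords = _check_coords(topology, coords)
    v, _ = _energy_forces(coords, *_kernel_args(topology))
    return float(v)


def forces(topology: GoTopology, coords: np.ndarray) -> np.ndarray:
    """Analytic forces −∇V, per bead, in ε/Å."""
    coords = _check_coords(topology, coords)
    _, f = _energy_forces(coords, *_kernel_args(topology))
    return f


def _check_coords(topology: GoTopology, coords: np.ndarray) -> np.ndarray:
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (topology.n_residues, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match topology "
            f"({topology.n_residues} residues)")
    return coords


def compute_q(topology: GoTopology, coords: np.ndarray,
              gamma: float = DEFAULT_GAMMA) -> tuple[float, np.ndarray]:
    """Fraction of native contacts formed, plus per-contact flags.

    A contact counts as formed when its distance is below gamma times the
    native distance.  A topology without native contacts reports Q = 1 by
    convention (logged), avoiding a 0/0.
    """
    if gamma <= 1.0:
        raise ValueError("gamma must exceed 1")
    coords = _check_coords(topology, coords)
    if topology.n_contacts == 0:
        logger.warning("topology has no native contacts; Q defined as 1.0")
        return 1.0, np.zeros(0, dtype=bool)
    d = np.linalg.norm(coords[topology.contacts[:, 0]]
                       - coords[topology.contacts[:, 1]], axis=1)
    formed = d < gamma * topology.contact_r0
    return float(formed.mean()), formed


def rmsd(coords: np.ndarray, ref: np.ndarray, superpose: bool = True) -> float:
    """RMSD in Å, after optimal rigid-body superposition if requested."""
    coords = np.asarray(coords, float)
    ref = np.asarray(ref, float)
    if coords.shape != ref.shape:
        raise ValueError("conformations differ in shape")
    if superpose:
        coords = superpose_kabsch(coords, ref)
    return float(np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=1))))


def superpose_kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superposition of mobile onto ref (Kabsch, via SVD)."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    u, _, vt = np.linalg.svd(mc.T @ rc)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    return mc @ rot + ref.mean(axis=0)


def radius_of_gyration(coords: np.ndarray) -> float:
    coords = np.asarray(coords, float)
    return float(np.sqrt(np.mean(
        np.sum((coords - coords.mean(axis=0)) ** 2, axis=1))))


def rmsf(trajectory: Trajectory, discard_first: float = 0.0,
         superpose: bool = True) -> np.ndarray:
    """Per-residue fluctuation about the mean structure (Å).

    The first ``discard_first`` fraction of frames is dropped as
    equilibration; each retained frame is superposed onto the mean
    structure once, the mean recomputed, and fluctuations taken about it.
    """
    if not 0.0 <= discard_first < 1.0:
        raise ValueError("discard_first must be in [0, 1)")
    start = int(np.floor(trajectory.n_frames * discard_first))
    frames = trajectory.frames[start:]
    if len(frames) < 2:
        raise ValueError("need at least 2 retained frames for RMSF")
    mean = frames.mean(axis=0)
    if superpose:
        frames = np.array([superpose_kabsch(fr, mean) for fr in frames])
        mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

def run_langevin(topology: GoTopology, start: np.ndarray,
                 config: SimulationConfig,
                 gamma: float = DEFAULT_GAMMA) -> Trajectory:
    """Seeded constant-temperature BAOAB run.

    Frames (with potential energy, kinetic energy and Q) are recorded every
    ``save_every`` steps.  The single integer seed expands through numpy's
    SeedSequence, so the same (topology, start, config) always reproduces
    the same trajectory bit-for-bit.
    """
    x = _check_coords(topology, start).copy()
    if topology.n_contacts == 0:
        logger.warning(
            "simulating a topology without native contacts; Q will be 1.0")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    dt = config.timestep
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt(config.temperature * (1.0 - c1 * c1))
    args = _kernel_args(topology)
    n = topology.n_residues

    vel = rng.standard_normal((n, 3)) * np.sqrt(config.temperature)
    _, f = _energy_forces(x, *args)

    n_frames = config.n_steps // config.save_every
    frames = np.empty((n_frames, n, 3))
    energies = np.empty(n_frames)
    kinetic = np.empty(n_frames)
    q_values = np.empty(n_frames)
    for fr in range(n_frames):
        normals = rng.standard_normal((config.save_every, n, 3))
        x, vel, f, v_pot = _baoab_chunk(x, vel, f, normals, dt, c1, c2, *args)
        if not np.isfinite(v_pot) or np.max(np.abs(x)) > 1e6:
            raise RuntimeError(
                f"simulation blew up at step {(fr + 1) * config.save_every}; "
                "reduce the timestep")
        frames[fr] = x
        energies[fr] = v_pot
        kinetic[fr] = 0.5 * float(np.sum(vel * vel))
        q_values[fr], _ = compute_q(topology, x, gamma) \
            if topology.n_contacts else (1.0, None)
    return Trajectory(frames=frames, energies=energies, q_values=q_values,
                      kinetic=kinetic, config=config, topology=topology)


def run_ladder(topology: GoTopology, start: np.ndarray,
               temperatures: np.ndarray, n_steps: int, seed: int,
               timestep: float = 0.0005, friction: float = 1.0,
               save_every: int = 100) -> list[Trajectory]:
    """One constant-temperature run per ladder rung, with split seeds."""
    children = np.random.SeedSequence(seed).spawn(len(temperatures))
    out = []
    for temp, child in zip(temperatures, children):
        cfg = SimulationConfig(
            temperature=float(temp), n_steps=n_steps, timestep=timestep,
            friction=friction, save_every=save_every,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        out.append(run_langevin(topology, start, cfg))
    return out


# ---------------------------------------------------------------------------
# Trajectory I/O: multi-frame XYZ plus TSV sidecar
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, outdir: str | Path,
                     stem: str = "traj") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = traj.topology.n_residues
    with open(outdir / f"{stem}.xyz", "w") as fh:
        for fr, step in zip(traj.frames, traj.steps):
            fh.write(f"{n}\nstep {step}\n")
            for row in fr:
                fh.write(f"CA {row[0]:.4f} {row[1]:.4f} {row[2]:.4f}\n")
    pd.DataFrame({"step": traj.steps, "energy": traj.energies,
                  "kinetic": traj.kinetic, "q": traj.q_values}).to_csv(
        outdir / f"{stem}.tsv", sep="\t", index=False)


def read_trajectory_sidecar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_trajectory_xyz(path: str | Path) -> np.ndarray:
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            frames.append([list(map(float, fh.readline().split()[1:4]))
                           for _ in range(n)])
    return np.asarray(frames)
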