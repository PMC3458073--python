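"""Synthetic fixtures with analytically known ground truth.

Everything the pipeline consumes can be generated here: toy Cα chains
whose contact maps are provable by pair enumeration, PDB text for the
reader, two-state denaturation curves from the exact signal models, and
Boltzmann samples of an analytic two-level system for validating WHAM.
All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structure import CalphaStructure
from .unfolding import ChemicalFit, ThermalFit, chem_signal, thermal_signal

CA_SPACING = 3.8        # Å, consecutive Cα distance


def make_u_chain() -> CalphaStructure:
    """Six beads folded into a flat U: a desk-scale contact-map fixture.

    Exactly two native contacts exist under the 4.0–6.0 Å / separation >= 4
    rule: pairs (1,5) and (2,6) in 1-based numbering, both at 3.8·√2 Å.
    The (1,6) pair is closer than 4 Å and is excluded.
    """
    coords = np.array([
        [0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 0.0, 0.0],
        [7.6, 3.8, 0.0], [3.8, 3.8, 0.0], [0.0, 3.8, 0.0]])
    return CalphaStructure(
        residue_ids=np.arange(1, 7), residue_names=["GLY"] * 6,
        coords=coords, chain_id="A", label="u-chain")


def make_straight_chain(n: int = 10, start_id: int = 1) -> CalphaStructure:
    """Collinear chain at 3.8 Å spacing: zero native contacts by geometry."""
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * CA_SPACING
    return CalphaStructure(
        residue_ids=np.arange(start_id, start_id + n),
        residue_names=["GLY"] * n, coords=coords, chain_id="A",
        label=f"straight-{n}")


def make_helix_hairpin(n: int = 30, seed: int = 0) -> CalphaStructure:
    """Compact two-strand hairpin with a packed tail, a toy folded domain.

    Two antiparallel zigzag strands (3.8 Å virtual bonds, ~143° virtual
    bond angles, strand midlines 5.6 Å apart so cross-strand pairs fall
    inside the 4–6 Å contact window) form the core; the last ⌈0.15·n⌉
    residues run back through the groove between the strands, 4.2 Å above
    the plane and offset half a grid step, where each tail bead bridges
    beads of both strands (~3 contacts per bead).  The tail is therefore
    contact-dense relative to the core — deleting it removes a
    disproportionate share of the stabilizing energy, like a C-terminal
    region locking into a surface groove — while the three-bead floppy
    linker attaching it carries enough conformational entropy that the
    tail still un-docks at a lower temperature than the core melts.  The
    zigzag avoids collinear triples, so every virtual dihedral is well
    defined.  The geometry is analytic — the seed is accepted for
    interface uniformity but no randomness is used — and the contact map
    is exactly enumerable.
    """
    if not 20 <= n <= 60:
        raise ValueError("n must be in [20, 60]")
    a = CA_SPACING
    zig = 1.2                              # zigzag amplitude, Å
    h = float(np.sqrt(a * a - zig * zig))  # x advance per bond
    sep = 5.6                              # strand midline separation
    tail_z = 4.2                           # tail height above the plane
    m_tail = int(np.ceil(0.15 * n))
    n_rest = n - m_tail - 4                # one turn bead + three connectors
    n1 = (n_rest + 1) // 2
    n2 = n_rest - n1
    coords = []
    # strand 1 along +x in the z = 0 plane
    for i in range(n1):
        coords.append([i * h, zig * (i % 2), 0.0])
    xe = (n1 - 1) * h
    # turn bead bridging to strand 2
    coords.append([xe + 2.6, sep / 2.0, 0.5])
    # strand 2 back along -x, midline at y = sep
    for j in range(n2):
        coords.append([xe - j * h, sep + zig * (j % 2), 0.0])
    # three-bead floppy linker descending into the groove
    x2 = xe - (n2 - 1) * h
    coords.append([x2 - 3.0, 4.9, 1.4])
    coords.append([x2 - 5.2, 3.6, 3.0])
    coords.append([x2 - 1.6, 3.0, 4.1])
    # tail along +x through the inter-strand groove, half a step offset
    for k in range(m_tail):
        coords.append([x2 + (k + 0.5) * h, sep / 2.0, tail_z])
    coords = np.asarray(coords)
    return CalphaStructure(
        residue_ids=np.arange(1, n + 1), residue_names=["GLY"] * n,
        coords=coords, chain_id="A", label=f"helix-hairpin-{n}")


def tail_region(structure: CalphaStructure) -> tuple[int, int]:
    """Author-id range of the packed tail of a helix-hairpin fixture."""
    n = structure.n_residues
    m_tail = int(np.ceil(0.15 * n))
    ids = structure.residue_ids
    return int(ids[n - m_tail]), int(ids[-1])


def write_pdb(structure: CalphaStructure) -> str:
    """Serialize a Cα structure as standard PDB ATOM records."""
    if structure.n_residues > 99999:
        raise ValueError("too many atoms for PDB format")
    lines = []
    for serial, (rid, rname, xyz) in enumerate(
            zip(structure.residue_ids, structure.residue_names,
                structure.coords), start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  {rname:<3s} {structure.chain_id}"
            f"{rid:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00           C")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Denaturation curves
# ---------------------------------------------------------------------------

def make_chem_curve(params: ChemicalFit, x: np.ndarray,
                    noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Two-state chemical unfolding curve, optionally with Gaussian noise."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty denaturant grid")
    s = chem_signal(x, params)
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise_sd, x.shape)
    return pd.DataFrame({"x": x, "signal": s})


def make_thermal_curve(params: ThermalFit, temps_K: np.ndarray,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Two-state thermal melting curve on a Kelvin grid."""
    temps_K = np.asarray(temps_K, float)
    if temps_K.size == 0:
        raise ValueError("empty temperature grid")
    s = thermal_signal(temps_K, params)
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise_sd,
                                                   temps_K.shape)
    return pd.DataFrame({"T_K": temps_K, "signal": s})


# ---------------------------------------------------------------------------
# Two-level system for WHAM validation
# ---------------------------------------------------------------------------

def two_level_p_excited(dE: float, g: float, T: float) -> float:
    """Exact excited-state occupation g·e^(−dE/T) / (1 + g·e^(−dE/T))."""
    w = g * np.exp(-dE / T)
    return w / (1.0 + w)


def make_two_level_samples(dE: float, g: int, temperatures: np.ndarray,
                           n_per_T: int, seed: int = 0) -> list[np.ndarray]:
    """Exact Boltzmann energy samples of a two-level system.

    Ground level at E = 0 with degeneracy 1; excited level at E = dE with
    degeneracy g.  Returns one energy array per temperature.
    """
    if dE <= 0:
        raise ValueError("dE must be positive")
    if g < 1:
        raise ValueError("degeneracy must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for t in np.asarray(temperatures, float):
        p = two_level_p_excited(dE, g, t)
        out.append(np.where(rng.random(n_per_T) < p, dE, 0.0))
    return out
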