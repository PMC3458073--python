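"""Cα structures and structure-based (Gō) topologies.

A protein is reduced to one bead per residue, centred on the Cα position.
The native structure defines every reference value of the potential: bond
lengths, bond angles, dihedrals, and the native contact map.  A native
contact is a Cα pair at 4.0–6.0 Å with sequence separation of at least
four positions; closer-in-sequence pairs are already restrained by the
bonded terms and are excluded.

Units: coordinates in Å; energies in the reduced contact energy ε (ε = 1),
k_B = 1, bead masses 1.  Force constants default to K_r = 100ε,
K_θ = 20ε, K_Φ(1) = ε, K_Φ(3) = 0.5ε.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("gofold")

# Native-contact distance window (Å, Cα–Cα) and minimum sequence separation.
CONTACT_RMIN = 4.0
CONTACT_RMAX = 6.0
CONTACT_MIN_SEP = 4

# Sanity window for consecutive Cα distances (Å).
BOND_SANE_MIN = 2.0
BOND_SANE_MAX = 4.5

DEFAULT_K_R = 100.0
DEFAULT_K_THETA = 20.0
DEFAULT_K_PHI1 = 1.0
DEFAULT_K_PHI3 = 0.5
DEFAULT_SIGMA_NONNATIVE = 4.0  # Å, excluded-volume radius for non-native pairs


class StructureError(ValueError):
    """Raised for malformed or unsupported structure input."""


@dataclasses.dataclass
class CalphaStructure:
    """Ordered Cα records for a single chain.

    ``residue_ids`` keep the author numbering of the source PDB so that a
    selection such as "residues 196–210" means exactly what the depositor
    numbered, including offsets.
    """

    residue_ids: np.ndarray          # (n,) int, strictly increasing
    residue_names: list[str]         # 3-letter codes
    coords: np.ndarray               # (n, 3) float, Å
    chain_id: str = "A"
    label: str = ""

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def validate(self, bond_window: tuple[float, float] | None = None) -> None:
        n = len(self.residue_ids)
        if n < 2:
            raise StructureError("structure needs at least 2 residues")
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if len(self.residue_names) != n:
            raise StructureError("residue_names length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if np.any(np.diff(self.residue_ids) <= 0):
            raise StructureError("residue_ids must be strictly increasing")
        lo, hi = bond_window or (BOND_SANE_MIN, BOND_SANE_MAX)
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any((d <= lo) | (d >= hi)):
            bad = int(np.argmax((d <= lo) | (d >= hi)))
            raise StructureError(
                f"consecutive Calpha distance {d[bad]:.2f} A between residues "
                f"{self.residue_ids[bad]} and {self.residue_ids[bad + 1]} is "
                f"outside the sanity window ({lo}, {hi}) A"
            )

    def index_of(self, residue_id: int) -> int:
        pos = np.flatnonzero(self.residue_ids == residue_id)
        if pos.size == 0:
            raise StructureError(f"residue id {residue_id} not in structure")
        return int(pos[0])


@dataclasses.dataclass
class GoTopology:
    """Bonded reference values plus the native contact map of a Gō model.

    Contact pairs are stored as 0-based chain positions with i < j; the
    sequence-separation rule uses chain position, which for a contiguous
    chain coincides with author-numbering differences.
    """

    n_residues: int
    bond_r0: np.ndarray          # (n-1,) Å
    angle_theta0: np.ndarray     # (n-2,) rad
    dihedral_phi0: np.ndarray    # (n-3,) rad
    contacts: np.ndarray         # (m, 2) int, 0-based positions, i < j
    contact_r0: np.ndarray       # (m,) Å
    residue_ids: np.ndarray      # (n,) author numbering, for region selections
    excluded_pairs: np.ndarray | None = None  # sub-4 Å native pairs, no term
    dihedral_weight: np.ndarray | None = None  # 0 masks degenerate dihedrals
    epsilon: float = 1.0
    k_r: float = DEFAULT_K_R
    k_theta: float = DEFAULT_K_THETA
    k_phi1: float = DEFAULT_K_PHI1
    k_phi3: float = DEFAULT_K_PHI3
    sigma_nonnative: float = DEFAULT_SIGMA_NONNATIVE

    @property
    def n_contacts(self) -> int:
        return len(self.contact_r0)

    def nonnative_pairs(self) -> np.ndarray:
        """Pairs with sequence separation >= 4 carrying the r⁻¹² repulsion.

        Native contacts are excluded, as are the rare pairs that sit
        closer than 4 Å in the native reference: giving those the σ0 = 4 Å
        repulsion would push the native conformation off the potential's
        minimum, against the Gō construction.
        """
        n = self.n_residues
        ii, jj = np.triu_indices(n, k=CONTACT_MIN_SEP)
        pairs = np.column_stack([ii, jj])
        skip = set(map(tuple, self.contacts.tolist()))
        if self.excluded_pairs is not None:
            skip |= set(map(tuple, self.excluded_pairs.tolist()))
        if skip:
            keep = [tuple(p) not in skip for p in pairs.tolist()]
            pairs = pairs[np.asarray(keep, dtype=bool)]
        return pairs


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_pdb_calpha(pdb_text: str, chain: str = "A",
                    model_index: int = 0, label: str = "") -> CalphaStructure:
    """Extract one Cα bead per residue from PDB-format text.

    Takes the requested model and chain only; of alternate locations, the
    blank and 'A' altlocs are accepted.  Insertion codes are rejected
    because author numbering is used for residue selections downstream.
    HETATM records are ignored.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no models in PDB text")
    if model_index >= len(st):
        raise StructureError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    names = [ch.name for ch in model]
    found = None
    for ch in model:
        if ch.name == chain:
            found = ch
            break
    if found is None:
        raise StructureError(
            f"chain {chain!r} not found; available chains: {names}")

    ids: list[int] = []
    resnames: list[str] = []
    coords: list[list[float]] = []
    for res in found:
        if res.het_flag == "H":
            continue
        ca_atoms = [a for a in res if a.name == "CA"]
        if not ca_atoms:
            continue
        if res.seqid.icode not in (" ", "\0", ""):
            raise StructureError(
                f"insertion code {res.seqid.icode!r} at residue "
                f"{res.seqid.num} is not supported")
        kept = [a for a in ca_atoms if a.altloc in ("", "\0", "A")]
        if not kept:
            raise StructureError(
                f"residue {res.seqid.num}: CA has only non-A altlocs")
        if len(kept) > 1:
            raise StructureError(
                f"residue {res.seqid.num}: multiple acceptable CA altlocs")
        a = kept[0]
        if ids and res.seqid.num == ids[-1]:
            raise StructureError(
                f"duplicate residue number {res.seqid.num} in chain {chain}")
        ids.append(res.seqid.num)
        resnames.append(res.name)
        coords.append([a.pos.x, a.pos.y, a.pos.z])
    if not ids:
        raise StructureError(f"no CA atom records in chain {chain!r}")
    return CalphaStructure(
        residue_ids=np.asarray(ids), residue_names=resnames,
        coords=np.asarray(coords), chain_id=chain,
        label=label or f"chain {chain}")


def truncate(structure: CalphaStructure, keep_first: int,
             keep_last: int) -> CalphaStructure:
    """Keep the contiguous residue range [keep_first, keep_last] (author ids)."""
    if keep_first > keep_last:
        raise StructureError("keep_first must be <= keep_last")
    i0 = structure.index_of(keep_first)
    i1 = structure.index_of(keep_last)
    return CalphaStructure(
        residue_ids=structure.residue_ids[i0:i1 + 1].copy(),
        residue_names=list(structure.residue_names[i0:i1 + 1]),
        coords=structure.coords[i0:i1 + 1].copy(),
        chain_id=structure.chain_id,
        label=f"{structure.label}[{keep_first}-{keep_last}]",
    )


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
              p3: np.ndarray) -> float:
    """IUPAC signed dihedral of the four points, in (-pi, pi]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    return float(np.arctan2(y, x))


def build_topology(structure: CalphaStructure, epsilon: float = 1.0,
                   **overrides: float) -> GoTopology:
    """Build the Gō topology whose minimum is the input conformation.

    Native contacts are exactly the Cα pairs with chain-position separation
    >= 4 and distance within [4.0, 6.0] Å.  Keyword overrides may replace
    any force-field constant (``k_r``, ``k_theta``, ``k_phi1``, ``k_phi3``,
    ``sigma_nonnative``).
    """
    structure.validate()
    x = structure.coords
    n = len(x)
    if n < 4:
        raise StructureError("need at least 4 residues to define a dihedral")

    bond_r0 = np.linalg.norm(np.diff(x, axis=0), axis=1)
    angle_theta0 = np.array([_angle(x[i - 1], x[i], x[i + 1])
                             for i in range(1, n - 1)])
    dihedral_phi0 = np.array([_dihedral(x[i - 1], x[i], x[i + 1], x[i + 2])
                              for i in range(1, n - 2)])
    # a dihedral flanked by a straight (or folded-back) virtual angle has no
    # defined reference value; its torsional term is masked out
    sin_flank = np.abs(np.sin(angle_theta0))
    degenerate = np.minimum(sin_flank[:-1], sin_flank[1:]) < 1e-6
    dihedral_weight = np.where(degenerate, 0.0, 1.0)
    if degenerate.any():
        logger.info("%d dihedral(s) with degenerate native geometry masked",
                    int(degenerate.sum()))

    ii, jj = np.triu_indices(n, k=CONTACT_MIN_SEP)
    d = np.linalg.norm(x[ii] - x[jj], axis=1)
    mask = (d >= CONTACT_RMIN) & (d <= CONTACT_RMAX)
    contacts = np.column_stack([ii[mask], jj[mask]]).astype(int)
    contact_r0 = d[mask]
    close = d < CONTACT_RMIN
    excluded = np.column_stack([ii[close], jj[close]]).astype(int)
    if len(excluded):
        logger.info("%d pair(s) closer than %.1f A in the native reference "
                    "excluded from the repulsion list", len(excluded),
                    CONTACT_RMIN)

    allowed = {"k_r", "k_theta", "k_phi1", "k_phi3", "sigma_nonnative"}
    bad = set(overrides) - allowed
    if bad:
        raise TypeError(f"unknown force-field overrides: {sorted(bad)}")
    return GoTopology(
        n_residues=n, bond_r0=bond_r0, angle_theta0=angle_theta0,
        dihedral_phi0=dihedral_phi0, contacts=contacts,
        contact_r0=contact_r0, residue_ids=structure.residue_ids.copy(),
        excluded_pairs=excluded, dihedral_weight=dihedral_weight,
        epsilon=float(epsilon), **overrides)


# ---------------------------------------------------------------------------
# Topology serialization (plain-text table set)
# ---------------------------------------------------------------------------

def write_topology(topology: GoTopology, outdir: str | Path) -> None:
    """Write a topology as a directory of TSV tables plus a JSON header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_residues": topology.n_residues,
        "epsilon": topology.epsilon,
        "k_r": topology.k_r, "k_theta": topology.k_theta,
        "k_phi1": topology.k_phi1, "k_phi3": topology.k_phi3,
        "sigma_nonnative": topology.sigma_nonnative,
        "residue_ids": topology.residue_ids.tolist(),
        "excluded_pairs": ([] if topology.excluded_pairs is None
                           else topology.excluded_pairs.tolist()),
    }
    (outdir / "topology.json").write_text(json.dumps(meta, indent=1))
    pd.DataFrame({"i": np.arange(topology.n_residues - 1),
                  "r0_A": topology.bond_r0}).to_csv(
        outdir / "bonds.tsv", sep="\t", index=False)
    pd.DataFrame({"i": np.arange(1, topology.n_residues - 1),
                  "theta0_rad": topology.angle_theta0}).to_csv(
        outdir / "angles.tsv", sep="\t", index=False)
    weight = (topology.dihedral_weight if topology.dihedral_weight
              is not None else np.ones_like(topology.dihedral_phi0))
    pd.DataFrame({"i": np.arange(1, topology.n_residues - 2),
                  "phi0_rad": topology.dihedral_phi0,
                  "weight": weight}).to_csv(
        outdir / "dihedrals.tsv", sep="\t", index=False)
    pd.DataFrame({"i": topology.contacts[:, 0] if topology.n_contacts else [],
                  "j": topology.contacts[:, 1] if topology.n_contacts else [],
                  "r0_A": topology.contact_r0}).to_csv(
        outdir / "contacts.tsv", sep="\t", index=False)


def read_topology(indir: str | Path) -> GoTopology:
    indir = Path(indir)
    meta = json.loads((indir / "topology.json").read_text())
    bonds = pd.read_csv(indir / "bonds.tsv", sep="\t")
    angles = pd.read_csv(indir / "angles.tsv", sep="\t")
    dihedrals = pd.read_csv(indir / "dihedrals.tsv", sep="\t")
    contacts = pd.read_csv(indir / "contacts.tsv", sep="\t")
    pairs = contacts[["i", "j"]].to_numpy(dtype=int).reshape(-1, 2)
    return GoTopology(
        n_residues=meta["n_residues"],
        bond_r0=bonds["r0_A"].to_numpy(),
        angle_theta0=angles["theta0_rad"].to_numpy(),
        dihedral_phi0=dihedrals["phi0_rad"].to_numpy(),
        dihedral_weight=(dihedrals["weight"].to_numpy()
                         if "weight" in dihedrals else None),
        contacts=pairs, contact_r0=contacts["r0_A"].to_numpy(),
        residue_ids=np.asarray(meta["residue_ids"], dtype=int),
        excluded_pairs=np.asarray(meta.get("excluded_pairs", []),
                                  dtype=int).reshape(-1, 2),
        epsilon=meta["epsilon"], k_r=meta["k_r"], k_theta=meta["k_theta"],
        k_phi1=meta["k_phi1"], k_phi3=meta["k_phi3"],
        sigma_nonnative=meta["sigma_nonnative"])
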