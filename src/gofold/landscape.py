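"""Native-contact landscape analysis: region decomposition and substates.

The native contact set is split into contacts touching a region of
interest (for frataxin, the C-terminal region, residues 196–210) and the
remaining core contacts.  Per-frame Q is decomposed accordingly, joint
(Q_core, Q_region) log-probability maps are built, frames are classified
into native substates — N1 (core folded, region bound), N2 (core folded,
region unbound), U (unfolded) — and contact-formation probabilities are
computed for frame selections such as the transition-state ensemble
(frames near the free-energy barrier at Q ≈ 0.5).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .simulate import DEFAULT_GAMMA, Trajectory
from .structure import GoTopology

logger = logging.getLogger("gofold")

# Default substate thresholds on (Q_core, Q_region)
N_CORE_FOLDED = 0.7
N_REGION_BOUND = 0.5
U_CORE = 0.3

TSE_Q_CENTER = 0.5
TSE_HALF_WIDTH = 0.05


@dataclasses.dataclass
class ContactPartition:
    """Disjoint, exhaustive split of a topology's native contacts."""

    region_first: int               # author residue ids
    region_last: int
    ctr_idx: np.ndarray             # indices into topology.contacts
    core_idx: np.ndarray
    topology: GoTopology

    @property
    def n_ctr(self) -> int:
        return len(self.ctr_idx)

    @property
    def n_core(self) -> int:
        return len(self.core_idx)


def partition_contacts(topology: GoTopology, region_first: int,
                       region_last: int) -> ContactPartition:
    """Split contacts: a contact belongs to the region iff >= 1 partner does."""
    ids = topology.residue_ids
    in_region = (ids >= region_first) & (ids <= region_last)
    if not in_region.any():
        raise ValueError(
            f"region [{region_first}, {region_last}] contains no residues")
    pairs = topology.contacts.reshape(-1, 2)
    touches = in_region[pairs[:, 0]] | in_region[pairs[:, 1]]
    ctr_idx = np.flatnonzero(touches)
    core_idx = np.flatnonzero(~touches)
    if ctr_idx.size == 0:
        logger.warning("no native contacts touch the region "
                       "[%d, %d]", region_first, region_last)
    return ContactPartition(region_first=region_first,
                            region_last=region_last, ctr_idx=ctr_idx,
                            core_idx=core_idx, topology=topology)


def _formed_counts(frames: np.ndarray, topology: GoTopology,
                   idx: np.ndarray, gamma: float) -> np.ndarray:
    pairs = topology.contacts[idx]
    r0 = topology.contact_r0[idx]
    d = np.linalg.norm(frames[:, pairs[:, 0]] - frames[:, pairs[:, 1]],
                       axis=2)
    return (d < gamma * r0).sum(axis=1)


def q_decompose(trajectory: Trajectory, partition: ContactPartition,
                gamma: float = DEFAULT_GAMMA) -> pd.DataFrame:
    """Per-frame (Q_core, Q_region), each normalized by its own count.

    Also carries the integer formed-contact counts per component, through
    which the counting identity
    n_core·Q_core + n_region·Q_region = n_total·Q holds exactly frame by
    frame.  An empty component reports Q = 1 (same convention as the
    global Q of a contact-free topology), with a warning.
    """
    frames = trajectory.frames
    out = {}
    for name, idx in (("core", partition.core_idx),
                      ("ctr", partition.ctr_idx)):
        if idx.size == 0:
            logger.warning("empty %s contact subset; its Q reported as 1.0",
                           name)
            out[f"n_{name}_formed"] = np.zeros(len(frames), dtype=int)
            out[f"q_{name}"] = np.ones(len(frames))
        else:
            k = _formed_counts(frames, partition.topology, idx, gamma)
            out[f"n_{name}_formed"] = k
            out[f"q_{name}"] = k / idx.size
    return pd.DataFrame(out)[["q_core", "q_ctr", "n_core_formed",
                              "n_ctr_formed"]]


@dataclasses.dataclass
class JointMap:
    """log P over a (Q_core, Q_region) grid; empty bins are −inf."""

    core_edges: np.ndarray
    ctr_edges: np.ndarray
    logp: np.ndarray            # (n_core_bins, n_ctr_bins)
    counts: np.ndarray

    def marginal_core(self) -> np.ndarray:
        return self.counts.sum(axis=1) / self.counts.sum()


def joint_logprob_map(decomposed: pd.DataFrame,
                      bins: int = 25) -> JointMap:
    """Joint log relative frequency of (Q_core, Q_region) over [0,1]²."""
    if len(decomposed) < 100:
        logger.warning("joint map from only %d frames; expect noise",
                       len(decomposed))
    edges = np.linspace(0.0, 1.0 + 1e-12, bins + 1)
    h, ce, te = np.histogram2d(decomposed["q_core"], decomposed["q_ctr"],
                               bins=[edges, edges])
    with np.errstate(divide="ignore"):
        logp = np.where(h > 0, np.log(h / h.sum()), -np.inf)
    return JointMap(core_edges=ce, ctr_edges=te, logp=logp, counts=h)


def classify_substates(decomposed: pd.DataFrame,
                       core_folded: float = N_CORE_FOLDED,
                       region_bound: float = N_REGION_BOUND,
                       u_core: float = U_CORE) -> pd.Series:
    """Label frames N1 / N2 / U / other from (Q_core, Q_region).

    N1: core folded and region bound; N2: core folded, region unbound;
    U: core unfolded.  The thresholds are an explicit operationalization
    and are recorded in the Series attrs.
    """
    for name, th in (("core_folded", core_folded),
                     ("region_bound", region_bound), ("u_core", u_core)):
        if not 0.0 <= th <= 1.0:
            raise ValueError(f"threshold {name}={th} outside [0, 1]")
    qc = decomposed["q_core"].to_numpy()
    qt = decomposed["q_ctr"].to_numpy()
    labels = np.full(len(qc), "other", dtype=object)
    labels[qc <= u_core] = "U"
    labels[(qc >= core_folded) & (qt < region_bound)] = "N2"
    labels[(qc >= core_folded) & (qt >= region_bound)] = "N1"
    out = pd.Series(labels, name="substate")
    out.attrs["thresholds"] = {"core_folded": core_folded,
                               "region_bound": region_bound,
                               "u_core": u_core}
    return out


def contact_probability_matrix(frames: np.ndarray, topology: GoTopology,
                               gamma: float = DEFAULT_GAMMA) -> pd.DataFrame:
    """Formation probability of every native contact over selected frames.

    Returns a table (i, j as author residue ids, probability) plus the
    number of contributing frames in ``attrs``.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise ValueError(
            "no frames selected; widen the Q window of the selection")
    pairs = topology.contacts.reshape(-1, 2)
    d = np.linalg.norm(frames[:, pairs[:, 0]] - frames[:, pairs[:, 1]],
                       axis=2)
    prob = (d < gamma * topology.contact_r0).mean(axis=0)
    out = pd.DataFrame({
        "i": topology.residue_ids[pairs[:, 0]],
        "j": topology.residue_ids[pairs[:, 1]],
        "probability": prob,
    })
    out.attrs["n_frames"] = len(frames)
    return out


def select_tse_frames(trajectory: Trajectory,
                      q_center: float = TSE_Q_CENTER,
                      half_width: float = TSE_HALF_WIDTH) -> np.ndarray:
    """Frames with |Q − q_center| <= half_width (TSE selection at Tm)."""
    mask = np.abs(trajectory.q_values - q_center) <= half_width
    return trajectory.frames[mask]


def select_native_frames(trajectory: Trajectory,
                         q_min: float = 0.8) -> np.ndarray:
    return trajectory.frames[trajectory.q_values >= q_min]
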