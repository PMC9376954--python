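"""Structural order parameters and aggregate phase classification.

Two cluster-level descriptors distinguish aggregate morphologies:

* the end-to-end correlation parameter ``C_n``: the average of the squared
  dot products between the normalized backbone end-to-end vectors of all
  peptide pairs in a cluster,

      C_n = 1 / (M (M - 1)) * sum_{i != j} (n_i . n_j)^2 .

  It equals 1 exactly when all chains are pairwise parallel *or*
  antiparallel (the squared form is blind to the head/tail sign, matching
  the antiparallel-pair fibril motif) and averages 1/3 for isotropically
  random orientations;

* the backbone-backbone correlation parameter ``C_BB``: for each peptide i,
  the unit vectors u_ij from its backbone mass centre to the centres of its
  shell neighbours (0.8 <= r <= 2.4 nm) are compared pairwise through
  |u_ij . u_ik|, averaged over neighbour pairs and then over all peptides
  with at least two shell neighbours.  Collinear stacking (a ribbon) gives
  1; orthogonal neighbour directions give 0.

In the (C_n, C_BB) plane, single-ribbon fibrils occupy the high-C_BB
corner, multi-ribbon fibrils and annular structures combine high C_n with
intermediate C_BB, amyloid-glasses sit at intermediate order, and amorphous
aggregates at low order.  The default region boundaries are fitted to this
package's synthetic fixtures, not taken from any reference data, and are
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .system import Frame, Trajectory, minimum_image, system_energy
from .topology import Topology

#: Neighbour shell (nm) for the backbone-backbone correlation parameter.
DEFAULT_SHELL = (0.8, 2.4)


@dataclass
class OrderDescriptors:
    """(C_n, C_BB) pair for one cluster; NaN marks an undefined descriptor."""

    c_n: float
    c_bb: float
    cluster_size: int
    n_cbb_contributors: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.c_n) and np.isfinite(self.c_bb)


@dataclass
class PhaseBoundaries:
    """Threshold rules partitioning [0,1]^2 into the four phase regions.

    Provenance: fitted to this package's fixtures, not reference data.
    Evaluation order (ties resolve toward the more ordered label):
    single-ribbon if C_BB >= cbb_single; multi-ribbon/annular if
    C_n >= cn_multi and C_BB >= cbb_multi; amyloid-glass if C_n >= cn_glass
    or C_BB >= cbb_glass; else amorphous.
    """

    cbb_single: float = 0.8
    cn_multi: float = 0.6
    cbb_multi: float = 0.5
    cn_glass: float = 0.4
    cbb_glass: float = 0.4

    LABELS = ("amorphous", "amyloid-glass", "multi-ribbon/annular", "single-ribbon")


def unwrap_chain(frame: Frame, indices: np.ndarray) -> np.ndarray:
    """Chain coordinates made whole across the periodic boundary.

    Walks the beads in the given order, shifting each by whole box vectors
    so consecutive beads use the minimum-image displacement.
    """
    pos = frame.positions[indices]
    out = np.empty_like(pos)
    out[0] = pos[0]
    steps = minimum_image(np.diff(pos, axis=0), frame.box)
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out


def end_to_end_units(frame: Frame, topology: Topology,
                     cluster_members: np.ndarray) -> np.ndarray:
    """Normalized first-B-to-last-B vector of each peptide in the cluster.

    Terminal caps and side chains are excluded: the end-to-end vector runs
    along the backbone only.  Raises for a degenerate (zero-length) vector.
    """
    members = np.atleast_1d(np.asarray(cluster_members, dtype=int))
    if members.size == 0:
        raise ValueError("empty cluster")
    units = np.empty((len(members), 3))
    for a, chain in enumerate(members):
        bb = unwrap_chain(frame, topology.backbone_indices(int(chain)))
        v = bb[-1] - bb[0]
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError(f"degenerate end-to-end vector for peptide {chain}")
        units[a] = v / norm
    return units


def cn_parameter(units: np.ndarray) -> float:
    """End-to-end correlation parameter of a set of unit vectors (M >= 2)."""
    u = np.asarray(units, dtype=float)
    m = len(u)
    if m < 2:
        return float("nan")
    g = u @ u.T
    total = float(np.sum(g * g)) - float(np.sum(np.diag(g) ** 2))
    return total / (m * (m - 1))


def backbone_centers(frame: Frame, topology: Topology,
                     cluster_members: np.ndarray) -> np.ndarray:
    """Mass-weighted centre of each peptide's backbone (B) beads.

    Each chain is unwrapped before averaging, so a chain split across the
    periodic boundary gets the centre of its whole image.
    """
    members = np.atleast_1d(np.asarray(cluster_members, dtype=int))
    masses = topology.masses
    centers = np.empty((len(members), 3))
    for a, chain in enumerate(members):
        idx = topology.backbone_indices(int(chain))
        bb = unwrap_chain(frame, idx)
        w = masses[idx]
        centers[a] = (bb * w[:, None]).sum(axis=0) / w.sum()
    return centers


def cbb_parameter(frame: Frame, topology: Topology,
                  cluster_members: np.ndarray,
                  shell: tuple[float, float] = DEFAULT_SHELL) -> tuple[float, int]:
    """Backbone-backbone correlation parameter of one cluster.

    Returns ``(value, n_contributors)``; the value is NaN (undefined) when
    no peptide has at least two shell neighbours.
    """
    centers = backbone_centers(frame, topology, cluster_members)
    return cbb_from_centers(centers, frame.box, shell)


def cbb_from_centers(centers: np.ndarray, box: float,
                     shell: tuple[float, float] = DEFAULT_SHELL) -> tuple[float, int]:
    """C_BB from backbone centres directly (shared by tests and fixtures)."""
    m = len(centers)
    lo, hi = shell
    per_peptide = []
    for i in range(m):
        d = minimum_image(np.delete(centers, i, axis=0) - centers[i], box)
        r = np.linalg.norm(d, axis=1)
        sel = (r >= lo) & (r <= hi)
        if np.count_nonzero(sel) < 2:
            continue
        u = -d[sel] / r[sel][:, None]  # unit vectors from i toward neighbours
        g = np.abs(u @ u.T)
        k = len(u)
        per_peptide.append((g.sum() - np.trace(g)) / (k * (k - 1)))
    if not per_peptide:
        return float("nan"), 0
    return float(np.mean(per_peptide)), len(per_peptide)


def describe_cluster(frame: Frame, topology: Topology,
                     cluster_members: np.ndarray,
                     shell: tuple[float, float] = DEFAULT_SHELL) -> OrderDescriptors:
    """Both descriptors for one cluster."""
    members = np.atleast_1d(np.asarray(cluster_members, dtype=int))
    c_n = (cn_parameter(end_to_end_units(frame, topology, members))
           if len(members) >= 2 else float("nan"))
    c_bb, n_contrib = cbb_parameter(frame, topology, members, shell)
    return OrderDescriptors(c_n=c_n, c_bb=c_bb, cluster_size=len(members),
                            n_cbb_contributors=n_contrib)


def classify_phase(descriptors: OrderDescriptors,
                   boundaries: PhaseBoundaries | None = None) -> str:
    """Deterministic region lookup in the (C_n, C_BB) plane."""
    b = boundaries if boundaries is not None else PhaseBoundaries()
    if not descriptors.defined:
        return "unclassified"
    cn, cbb = descriptors.c_n, descriptors.c_bb
    if cbb >= b.cbb_single:
        return "single-ribbon"
    if cn >= b.cn_multi and cbb >= b.cbb_multi:
        return "multi-ribbon/annular"
    if cn >= b.cn_glass or cbb >= b.cbb_glass:
        return "amyloid-glass"
    return "amorphous"


def aggregate_energy_series(trajectory: Trajectory, topology: Topology, ff,
                            window: slice | None = None) -> tuple[float, float, np.ndarray]:
    """Windowed mean and standard deviation of the total potential energy.

    ``window`` is a slice over the trajectory's frames (default: all).
    Returns (mean, sd, per-frame energies).
    """
    frames = trajectory.frames[window] if window is not None else trajectory.frames
    if not frames:
        raise ValueError("empty frame window")
    energies = np.array([system_energy(f, topology, ff) for f in frames])
    return float(energies.mean()), float(energies.std(ddof=0)), energies
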