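"""Cutoff-based cluster identification and kinetic observables.

Two peptides are directly linked when any bead of one lies within the
contact cutoff (default 0.55 nm, i.e. 5.5 A, inclusive) of any bead of the
other, distances taken with the minimum-image convention.  Clusters are the
connected components of this link graph (single linkage), so the clustering
at a smaller cutoff always refines the clustering at a larger one.

All beads participate in the contact definition, including side-chain and
terminal beads (configurable via ``include_kinds``).

The kinetic observables are the number of free monomers n1, dimers n2,
trimers n3, and the total number of clusters of any size n_c = sum_i n_i,
tracked over time and averaged across repeat trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .forcefield import BeadKind
from .system import Frame, Trajectory, minimum_image
from .topology import Topology

#: Contact cutoff in nm (5.5 A).
DEFAULT_CUTOFF = 0.55


@dataclass
class ClusterAssignment:
    """Per-peptide cluster labels for one frame.

    Labels are contiguous integers starting at 0, ordered by first
    appearance along the peptide index.  ``sizes[k]`` is the number of
    peptides in cluster k.
    """

    labels: np.ndarray
    sizes: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.sizes.sum() != len(self.labels):
            raise ValueError("cluster sizes must sum to the number of peptides")

    @property
    def n_peptides(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def size_counts(self, n_max: int) -> np.ndarray:
        """n_i for i = 1..n_max as an array indexed [1..n_max] (entry 0 unused)."""
        counts = np.bincount(self.sizes, minlength=n_max + 1)
        return counts[: n_max + 1]


def _canonical_labels(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel components by first appearance; return (labels, sizes)."""
    labels = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[int(r)] = len(mapping)
        labels[i] = mapping[int(r)]
    sizes = np.bincount(labels, minlength=len(mapping))
    return labels, sizes


def find_clusters(frame: Frame, topology: Topology,
                  cutoff: float = DEFAULT_CUTOFF,
                  include_kinds: tuple[BeadKind, ...] | None = None) -> ClusterAssignment:
    """Single-linkage clusters of peptides under the contact cutoff.

    The production neighbour search uses a periodic k-d tree on wrapped
    coordinates; a pair straddling the box boundary at distance <= cutoff is
    linked.  ``include_kinds`` restricts which bead kinds define contacts
    (default: all four kinds).
    """
    n_chains = topology.n_chains
    chain_of = topology.chain_ids
    pos = frame.positions
    L = frame.box
    if include_kinds is not None:
        keep = np.array([k in include_kinds for k in topology.kinds])
        pos = pos[keep]
        chain_of = chain_of[keep]

    if cutoff < 0.5 * L:
        tree = cKDTree(np.mod(pos, L), boxsize=L)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            ci = chain_of[pairs[:, 0]]
            cj = chain_of[pairs[:, 1]]
            mask = ci != cj
            ci, cj = ci[mask], cj[mask]
        else:
            ci = cj = np.empty(0, dtype=int)
    else:
        # fall back to the all-pairs minimum-image path for tiny boxes
        ci, cj = _brute_force_chain_links(pos, chain_of, L, cutoff)

    g = sparse.coo_matrix((np.ones(len(ci)), (ci, cj)),
                          shape=(n_chains, n_chains))
    _, raw = connected_components(g, directed=False)
    labels, sizes = _canonical_labels(raw)
    return ClusterAssignment(labels=labels, sizes=sizes, time=frame.time)


def _brute_force_chain_links(pos: np.ndarray, chain_of: np.ndarray, L: float,
                             cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(len(pos), k=1)
    d = minimum_image(pos[iu] - pos[ju], L)
    close = np.einsum("ij,ij->i", d, d) <= cutoff * cutoff
    ci = chain_of[iu[close]]
    cj = chain_of[ju[close]]
    mask = ci != cj
    return ci[mask], cj[mask]


def find_clusters_brute_force(frame: Frame, topology: Topology,
                              cutoff: float = DEFAULT_CUTOFF) -> ClusterAssignment:
    """All-pairs minimum-image reference path (test oracle for find_clusters)."""
    ci, cj = _brute_force_chain_links(frame.positions, topology.chain_ids,
                                      frame.box, cutoff)
    g = sparse.coo_matrix((np.ones(len(ci)), (ci, cj)),
                          shape=(topology.n_chains, topology.n_chains))
    _, raw = connected_components(g, directed=False)
    labels, sizes = _canonical_labels(raw)
    return ClusterAssignment(labels=labels, sizes=sizes, time=frame.time)


# ---------------------------------------------------------------------------
# kinetic curves
# ---------------------------------------------------------------------------

@dataclass
class KineticCurves:
    """Time series of n1, n2, n3 and n_c with across-repeat statistics.

    ``mean[name]`` and ``sem[name]`` (standard deviation of the mean) are
    arrays on ``time_ns``; for single-source curves (one repeat, or an ODE
    solution) the SEM is zero.
    """

    time_ns: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_repeats: int = 1

    NAMES = ("n1", "n2", "n3", "nc")

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        for name in self.NAMES:
            if name not in self.mean:
                raise ValueError(f"missing curve {name!r}")
            self.mean[name] = np.asarray(self.mean[name], dtype=float)
            if name not in self.sem:
                self.sem[name] = np.zeros_like(self.mean[name])
            if len(self.mean[name]) != len(self.time_ns):
                raise ValueError("curve length must match time grid")


def census(assignment: ClusterAssignment) -> dict[str, int]:
    """n1, n2, n3 and n_c for one frame's cluster assignment."""
    sizes = assignment.sizes
    return {
        "n1": int(np.sum(sizes == 1)),
        "n2": int(np.sum(sizes == 2)),
        "n3": int(np.sum(sizes == 3)),
        "nc": int(len(sizes)),
    }


def curves_from_trajectories(trajectories: list[Trajectory], topology: Topology,
                             cutoff: float = DEFAULT_CUTOFF) -> KineticCurves:
    """Cluster-size census over an ensemble of repeat trajectories.

    Repeats are aligned to the first repeat's time grid by nearest-frame
    matching, then averaged; the spread is reported as the standard
    deviation of the mean.
    """
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    t_ref = trajectories[0].times
    per_repeat = {name: [] for name in KineticCurves.NAMES}
    for traj in trajectories:
        times = traj.times
        idx = np.abs(times[None, :] - t_ref[:, None]).argmin(axis=1)
        counts = {name: np.empty(len(t_ref)) for name in KineticCurves.NAMES}
        cache: dict[int, dict[str, int]] = {}
        for a, b in enumerate(idx):
            if b not in cache:
                cache[int(b)] = census(find_clusters(traj[int(b)], topology, cutoff))
            for name in KineticCurves.NAMES:
                counts[name][a] = cache[int(b)][name]
        for name in KineticCurves.NAMES:
            per_repeat[name].append(counts[name])

    r = len(trajectories)
    mean = {}
    sem = {}
    for name in KineticCurves.NAMES:
        arr = np.vstack(per_repeat[name])
        mean[name] = arr.mean(axis=0)
        sem[name] = (arr.std(axis=0, ddof=1) / np.sqrt(r)) if r > 1 else np.zeros(len(t_ref))
    return KineticCurves(time_ns=t_ref, mean=mean, sem=sem, n_repeats=r)
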