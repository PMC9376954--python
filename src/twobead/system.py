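"""Frames, trajectories, and the assembled potential energy with forces.

Coordinates are stored unwrapped; the minimum-image convention is applied
inside every distance computation, so the energy is invariant under shifting
any bead by a whole box vector.  A wrap utility is provided for export.

The nonbonded sum runs over all bead pairs except those connected by a
harmonic bond (the model's only exclusions).  Identical-terminus pairs
(TN-TN, TC-TC) use the purely repulsive potential; all other pairs the
standard 12-6 LJ.  Potentials are truncated at the cutoff and shifted to
zero there so the energy is continuous; forces are the exact negative
gradient of the implemented (shifted) energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forcefield import OVERLAP_FLOOR, BeadKind, ForceField
from .topology import Topology

logger = logging.getLogger(__name__)


@dataclass
class Frame:
    """Positions (nm), optional velocities (nm/ps), cubic box edge L (nm), time (ns)."""

    positions: np.ndarray
    box: float
    time: float = 0.0
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_beads, 3)")
        if self.box <= 0:
            raise ValueError("box edge must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.box, self.time,
                     None if self.velocities is None else self.velocities.copy())

    def wrapped(self) -> "Frame":
        """Copy with positions wrapped into [0, L)."""
        out = self.copy()
        out.positions = np.mod(out.positions, self.box)
        return out


@dataclass
class Trajectory:
    """Ordered sequence of frames plus free-form run metadata."""

    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# precomputed interaction arrays
# ---------------------------------------------------------------------------

class InteractionTables:
    """Vectorized parameter arrays for a (topology, force field) pair.

    Building the flat pair list once makes repeated energy/force evaluation
    (minimization, dynamics) cheap; systems here are at most a few thousand
    beads, so the dense i<j pair list is the right tool.
    """

    def __init__(self, topology: Topology, ff: ForceField):
        self.topology = topology
        self.ff = ff
        n = topology.n_beads

        # bonds
        bp = np.array(topology.bond_pairs, dtype=int).reshape(-1, 2)
        self.bond_i = bp[:, 0]
        self.bond_j = bp[:, 1]
        self.bond_k = np.array([ff.bonds[c].k_b for c in topology.bond_classes])
        self.bond_r0 = np.array([ff.bonds[c].r0 for c in topology.bond_classes])

        # angles
        at = np.array(topology.angle_triplets, dtype=int).reshape(-1, 3)
        self.ang_i = at[:, 0]
        self.ang_j = at[:, 1]
        self.ang_k = at[:, 2]
        self.ang_kt = np.array([ff.angles[c].k_theta for c in topology.angle_classes])
        theta0 = np.array([np.radians(ff.angles[c].theta0) for c in topology.angle_classes])
        self.ang_theta0 = theta0
        self.ang_cos0 = np.cos(theta0)

        # nonbonded: all i<j pairs minus exclusions
        iu, ju = np.triu_indices(n, k=1)
        excl = topology.exclusions
        if excl:
            keep = np.array([frozenset((int(a), int(b))) not in excl
                             for a, b in zip(iu, ju)])
            iu, ju = iu[keep], ju[keep]
        self.nb_i = iu
        self.nb_j = ju
        kinds = topology.kinds
        kind_id = np.array([{"B": 0, "S": 1, "TN": 2, "TC": 3}[k.value] for k in kinds])
        sig = np.empty((4, 4))
        eps = np.empty((4, 4))
        rep = np.zeros((4, 4), dtype=bool)
        order = [BeadKind.B, BeadKind.S, BeadKind.TN, BeadKind.TC]
        for a in range(4):
            for b in range(4):
                pp = ff.pair_params(order[a], order[b])
                sig[a, b] = pp.sigma
                eps[a, b] = pp.epsilon
                rep[a, b] = pp.repulsive_only
        self.nb_sigma = sig[kind_id[iu], kind_id[ju]]
        self.nb_eps = eps[kind_id[iu], kind_id[ju]]
        self.nb_rep = rep[kind_id[iu], kind_id[ju]]
        # potential shift at the cutoff (zero if shifting disabled)
        rc = ff.cutoff
        sr6c = (self.nb_sigma / rc) ** 6
        if ff.shift_at_cutoff:
            self.nb_shift = np.where(self.nb_rep,
                                     4.0 * self.nb_eps * sr6c ** 2,
                                     4.0 * self.nb_eps * (sr6c ** 2 - sr6c))
        else:
            self.nb_shift = np.zeros_like(sr6c)
        self.n_beads = n


def _accumulate(n: int, idx: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Sum 3-vectors onto beads: returns (n, 3)."""
    out = np.empty((n, 3))
    for a in range(3):
        out[:, a] = np.bincount(idx, weights=vec[:, a], minlength=n)
    return out


def system_energy_forces(frame: Frame, topology: Topology, ff: ForceField,
                         tables: InteractionTables | None = None,
                         mode: str = "full"):
    """Total potential energy with per-term breakdown, and per-bead forces.

    Parameters
    ----------
    mode
        "full" (default), "bonded_only", or "nonbonded_only".

    Returns
    -------
    (energy_terms, forces)
        ``energy_terms`` is a dict with keys "bond", "angle", "lj",
        "replj", "total" (kJ/mol) and an "overlap" flag set when any
        nonbonded pair distance falls below the hard floor; ``forces`` is an
        (n_beads, 3) array in kJ/mol/nm.
    """
    if frame.n_beads != topology.n_beads:
        raise ValueError(
            f"frame has {frame.n_beads} beads, topology {topology.n_beads}")
    t = tables if tables is not None else InteractionTables(topology, ff)
    pos = frame.positions
    box = frame.box
    n = topology.n_beads
    forces = np.zeros((n, 3))
    terms = {"bond": 0.0, "angle": 0.0, "lj": 0.0, "replj": 0.0, "overlap": False}

    if mode in ("full", "bonded_only"):
        # bonds
        d = minimum_image(pos[t.bond_i] - pos[t.bond_j], box)
        r = np.linalg.norm(d, axis=1)
        dr = r - t.bond_r0
        terms["bond"] = float(np.sum(0.5 * t.bond_k * dr * dr))
        # F_i = -k (r - r0) d/r
        fpair = (-t.bond_k * dr / r)[:, None] * d
        forces += _accumulate(n, t.bond_i, fpair)
        forces -= _accumulate(n, t.bond_j, fpair)

        # angles (cosine-harmonic or harmonic)
        u = minimum_image(pos[t.ang_i] - pos[t.ang_j], box)
        v = minimum_image(pos[t.ang_k] - pos[t.ang_j], box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.einsum("ij,ij->i", u, v) / (nu * nv)
        c = np.clip(c, -1.0, 1.0)
        # dc/dri and dc/drk
        dci = (v / nv[:, None] - c[:, None] * u / nu[:, None]) / nu[:, None]
        dck = (u / nu[:, None] - c[:, None] * v / nv[:, None]) / nv[:, None]
        if ff.angle_form == "cosine":
            terms["angle"] = float(np.sum(0.5 * t.ang_kt * (c - t.ang_cos0) ** 2))
            dV_dc = t.ang_kt * (c - t.ang_cos0)
        elif ff.angle_form == "harmonic":
            th = np.arccos(c)
            terms["angle"] = float(np.sum(0.5 * t.ang_kt * (th - t.ang_theta0) ** 2))
            s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
            dV_dc = -t.ang_kt * (th - t.ang_theta0) / s
        else:
            raise ValueError(f"unknown angle form: {ff.angle_form!r}")
        fi = -dV_dc[:, None] * dci
        fk = -dV_dc[:, None] * dck
        forces += _accumulate(n, t.ang_i, fi)
        forces += _accumulate(n, t.ang_k, fk)
        forces -= _accumulate(n, t.ang_j, fi + fk)

    if mode in ("full", "nonbonded_only") and len(t.nb_i):
        d = minimum_image(pos[t.nb_i] - pos[t.nb_j], box)
        r2 = np.einsum("ij,ij->i", d, d)
        rc2 = ff.cutoff ** 2
        within = r2 < rc2
        if np.any(within):
            d = d[within]
            r2 = r2[within]
            sig = t.nb_sigma[within]
            eps = t.nb_eps[within]
            rep = t.nb_rep[within]
            shift = t.nb_shift[within]
            if np.any(r2 < OVERLAP_FLOOR ** 2):
                terms["overlap"] = True
                logger.warning("overlapping beads: min pair distance %.4g nm",
                               float(np.sqrt(r2.min())))
                r2 = np.maximum(r2, 1e-12)
            inv_r2 = 1.0 / r2
            sr6 = (sig * sig * inv_r2) ** 3
            sr12 = sr6 * sr6
            e_att = 4.0 * eps * (sr12 - sr6)
            fr_att = (48.0 * sr12 - 24.0 * sr6) * eps * inv_r2
            if ff.repulsive_form == "r12":
                e_rep = 4.0 * eps * sr12 - shift
                fr_rep = 48.0 * sr12 * eps * inv_r2
            elif ff.repulsive_form == "wca":
                # LJ cut and shifted at its minimum: already zero beyond
                # 2^(1/6) sigma, so no cutoff shift is applied
                inside = r2 < (2.0 ** (1.0 / 3.0)) * sig * sig
                e_rep = np.where(inside, e_att + eps, 0.0)
                fr_rep = np.where(inside, fr_att, 0.0)
            else:
                raise ValueError(f"unknown repulsive form: {ff.repulsive_form!r}")
            e = np.where(rep, e_rep, e_att - shift)
            terms["replj"] = float(np.sum(e[rep]))
            terms["lj"] = float(np.sum(e[~rep]))
            fmag = np.where(rep, fr_rep, fr_att)
            fpair = fmag[:, None] * d
            ii = t.nb_i[within]
            jj = t.nb_j[within]
            forces += _accumulate(n, ii, fpair)
            forces -= _accumulate(n, jj, fpair)

    terms["total"] = terms["bond"] + terms["angle"] + terms["lj"] + terms["replj"]
    return terms, forces


def system_energy(frame: Frame, topology: Topology, ff: ForceField,
                  tables: InteractionTables | None = None,
                  mode: str = "full") -> float:
    """Total potential energy (kJ/mol)."""
    terms, _ = system_energy_forces(frame, topology, ff, tables, mode)
    return terms["total"]
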