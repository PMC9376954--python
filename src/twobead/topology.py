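"""Bead topology builder for single- and multi-chain peptide systems.

An n-residue chain carries n backbone beads B1..Bn, one side-chain bead S_i
bonded to each B_i, and two terminal caps: TN bonded to B1 and TC bonded to
Bn.  Bond classes are BB (backbone), BT (cap) and BS (side chain); angle
classes are BBB along the backbone and BBS between a backbone bond and a
side-chain bond.  Caps take part in no angle term.  Nonbonded interactions
are excluded exactly for directly bonded pairs, nothing more -- in
particular 1-3 pairs do interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import DEFAULT_BEAD_MASS, BeadKind


@dataclass(frozen=True)
class Bead:
    index: int
    kind: BeadKind
    chain: int
    residue: int
    mass: float = DEFAULT_BEAD_MASS


@dataclass
class Topology:
    """Beads, bonds, angles and the nonbonded exclusion set.

    ``bond_pairs``/``angle_triplets`` hold bead indices; the parallel
    ``*_classes`` lists name the parameter class of each term.
    """

    beads: list[Bead]
    bond_pairs: list[tuple[int, int]]
    bond_classes: list[str]
    angle_triplets: list[tuple[int, int, int]]
    angle_classes: list[str]
    n_residues: int = 0
    n_chains: int = 1

    exclusions: set[frozenset[int]] = field(init=False)

    def __post_init__(self) -> None:
        # excluded pairs == bonded pairs, by model definition
        self.exclusions = {frozenset(p) for p in self.bond_pairs}
        self.validate()

    # -- derived views -----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def kinds(self) -> list[BeadKind]:
        return [b.kind for b in self.beads]

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([b.chain for b in self.beads])

    def chain_indices(self, chain: int) -> np.ndarray:
        """Bead indices of one chain, in construction order."""
        return np.array([b.index for b in self.beads if b.chain == chain])

    def backbone_indices(self, chain: int) -> np.ndarray:
        """B-bead indices of one chain, N- to C-terminal order."""
        idx = [b.index for b in self.beads
               if b.chain == chain and b.kind is BeadKind.B]
        return np.array(sorted(idx))

    def validate(self) -> None:
        n = self.n_beads
        for i, j in self.bond_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond references unknown bead: ({i}, {j})")
        for t in self.angle_triplets:
            if not all(0 <= i < n for i in t):
                raise ValueError(f"angle references unknown bead: {t}")
        if len(self.bond_pairs) != len(self.bond_classes):
            raise ValueError("bond class list length mismatch")
        if len(self.angle_triplets) != len(self.angle_classes):
            raise ValueError("angle class list length mismatch")


def bond_class(kind_i: BeadKind, kind_j: BeadKind) -> str:
    kinds = {kind_i, kind_j}
    if kinds == {BeadKind.B}:
        return "BB"
    if BeadKind.S in kinds:
        return "BS"
    return "BT"


def angle_class(kind_i: BeadKind, kind_j: BeadKind, kind_k: BeadKind) -> str:
    return "BBS" if BeadKind.S in {kind_i, kind_j, kind_k} else "BBB"


def build_topology(n_residues: int, n_chains: int = 1,
                   mass: float = DEFAULT_BEAD_MASS) -> Topology:
    """Construct the bead graph for ``n_chains`` identical chains.

    Per chain and in index order: TN, B1, S1, B2, S2, ..., Bn, Sn, TC
    (2 n_residues + 2 beads).  Counts per chain: (n-1) BB bonds, 2 BT bonds,
    n BS bonds, (n-2) BBB angles and 2(n-1) BBS angles -- each side chain
    S_i forms one BBS angle with every existing backbone neighbour of B_i,
    so interior residues contribute two BBS angles and terminal residues
    one.

    Chains are topologically disjoint; chain k is chain 0 shifted by
    k * (2 n_residues + 2).
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2 (no backbone geometry otherwise)")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")

    beads: list[Bead] = []
    bond_pairs: list[tuple[int, int]] = []
    bond_classes: list[str] = []
    angle_triplets: list[tuple[int, int, int]] = []
    angle_classes: list[str] = []

    per_chain = 2 * n_residues + 2
    for c in range(n_chains):
        off = c * per_chain
        tn = off
        beads.append(Bead(tn, BeadKind.TN, c, 0, mass))
        b_idx: list[int] = []
        s_idx: list[int] = []
        for r in range(n_residues):
            bi = off + 1 + 2 * r
            si = bi + 1
            beads.append(Bead(bi, BeadKind.B, c, r, mass))
            beads.append(Bead(si, BeadKind.S, c, r, mass))
            b_idx.append(bi)
            s_idx.append(si)
        tc = off + per_chain - 1
        beads.append(Bead(tc, BeadKind.TC, c, n_residues - 1, mass))

        # bonds
        for r in range(n_residues - 1):
            bond_pairs.append((b_idx[r], b_idx[r + 1]))
            bond_classes.append("BB")
        bond_pairs.append((tn, b_idx[0]))
        bond_classes.append("BT")
        bond_pairs.append((b_idx[-1], tc))
        bond_classes.append("BT")
        for r in range(n_residues):
            bond_pairs.append((b_idx[r], s_idx[r]))
            bond_classes.append("BS")

        # angles
        for r in range(n_residues - 2):
            angle_triplets.append((b_idx[r], b_idx[r + 1], b_idx[r + 2]))
            angle_classes.append("BBB")
        for r in range(n_residues):
            if r > 0:
                angle_triplets.append((b_idx[r - 1], b_idx[r], s_idx[r]))
                angle_classes.append("BBS")
            if r < n_residues - 1:
                angle_triplets.append((b_idx[r + 1], b_idx[r], s_idx[r]))
                angle_classes.append("BBS")

    return Topology(beads=beads, bond_pairs=bond_pairs, bond_classes=bond_classes,
                    angle_triplets=angle_triplets, angle_classes=angle_classes,
                    n_residues=n_residues, n_chains=n_chains)
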