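"""Programmatic generators of reference configurations.

Every test and example configuration is generated in code: a dilute random
monomer gas, a parallel ribbon (the single-ribbon fibril motif), an
antiparallel chain pair (the basic pairing motif of glasses and fibrils),
an annular ring of chain pairs (the pore-like aggregate), and a dense
amorphous blob.  Each generator asserts its declared geometric property
before returning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import DEFAULT_CUTOFF, find_clusters
from .dynamics import chain_template, random_rotation
from .forcefield import ForceField, default_forcefield
from .order import cn_parameter, end_to_end_units
from .system import Frame, minimum_image
from .topology import Topology, build_topology

FIXTURE_KINDS = ("random_gas", "parallel_ribbon", "antiparallel_pair",
                 "annular_ring", "amorphous_blob")


@dataclass
class FixtureSpec:
    """Declarative description of a generated configuration.

    ``spacing`` is the chain-to-chain offset in ribbons and rings (nm);
    ``radius`` bounds the amorphous blob; ``gap`` is the backbone-to-
    backbone distance of the antiparallel pair.
    """

    kind: str
    n_chains: int = 10
    n_residues: int = 8
    box: float = 35.0
    spacing: float = 0.5
    radius: float = 2.5
    gap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")


def make_fixture(spec: FixtureSpec, ff: ForceField | None = None
                 ) -> tuple[Frame, Topology]:
    """Generate the configuration described by ``spec``.

    Returns the frame together with the matching multi-chain topology.
    """
    if ff is None:
        ff = default_forcefield()
    topology = build_topology(spec.n_residues, spec.n_chains)
    template = chain_template(spec.n_residues, ff)
    template = template - template.mean(axis=0)
    builder = {
        "random_gas": _random_gas,
        "parallel_ribbon": _parallel_ribbon,
        "antiparallel_pair": _antiparallel_pair,
        "annular_ring": _annular_ring,
        "amorphous_blob": _amorphous_blob,
    }[spec.kind]
    frame = builder(spec, template)
    _assert_property(spec, frame, topology)
    return frame, topology


def _place(template: np.ndarray, rotation: np.ndarray, origin: np.ndarray) -> np.ndarray:
    return template @ rotation.T + origin


def _rot_z180() -> np.ndarray:
    # the chain template lies in the xy-plane, so a 180 deg turn about z
    # reverses its end-to-end vector exactly
    return np.diag([-1.0, -1.0, 1.0])


def _random_gas(spec: FixtureSpec, template: np.ndarray) -> Frame:
    rng = np.random.default_rng(spec.seed)
    chains = [_place(template, random_rotation(rng), rng.uniform(0, spec.box, 3))
              for _ in range(spec.n_chains)]
    return Frame(np.concatenate(chains), box=spec.box)


def _parallel_ribbon(spec: FixtureSpec, template: np.ndarray) -> Frame:
    """Chains on a 1-D lattice along z, identical orientation.

    The stacking axis is perpendicular to the chain plane (the template lies
    in xy), so the nearest inter-chain bead distance equals the spacing
    exactly.
    """
    if spec.spacing <= 0:
        raise ValueError("ribbon spacing must be positive")
    origin = np.full(3, spec.box / 2.0)
    chains = [_place(template, np.eye(3), origin + [0.0, 0.0, k * spec.spacing])
              for k in range(spec.n_chains)]
    return Frame(np.concatenate(chains), box=spec.box)


def _antiparallel_pair(spec: FixtureSpec, template: np.ndarray) -> Frame:
    if spec.n_chains != 2:
        raise ValueError("antiparallel_pair requires n_chains = 2")
    origin = np.full(3, spec.box / 2.0)
    a = _place(template, np.eye(3), origin)
    b = _place(template, _rot_z180(), origin + [0.0, 0.0, spec.gap])
    return Frame(np.concatenate([a, b]), box=spec.box)


def _annular_ring(spec: FixtureSpec, template: np.ndarray) -> Frame:
    """Chains on a circle, backbones normal to the ring plane.

    Orientations alternate up/down so neighbours form antiparallel pairs,
    the arrangement seen in the pore-like (annular) aggregate.  The radius
    follows from the spacing so ring neighbours stay within the cluster
    cutoff.
    """
    n = spec.n_chains
    if n < 4:
        raise ValueError("annular_ring needs at least 4 chains")
    # orient the chain backbone along z
    rot_xz = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    radius = n * spec.spacing / (2.0 * np.pi)
    center = np.full(3, spec.box / 2.0)
    chains = []
    for k in range(n):
        phi = 2.0 * np.pi * k / n
        rot = rot_xz if k % 2 == 0 else rot_xz @ _rot_z180()
        origin = center + [radius * np.cos(phi), radius * np.sin(phi), 0.0]
        chains.append(_place(template, rot, origin))
    return Frame(np.concatenate(chains), box=spec.box)


def _amorphous_blob(spec: FixtureSpec, template: np.ndarray) -> Frame:
    """Dense random cluster: chain centres uniform in a sphere."""
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.box / 2.0)
    chains = []
    for _ in range(spec.n_chains):
        while True:
            p = rng.uniform(-spec.radius, spec.radius, 3)
            if p @ p <= spec.radius ** 2:
                break
        chains.append(_place(template, random_rotation(rng), center + p))
    return Frame(np.concatenate(chains), box=spec.box)


def _assert_property(spec: FixtureSpec, frame: Frame, topology: Topology) -> None:
    """Check the declared geometric property of each fixture kind."""
    members = np.arange(spec.n_chains)
    if spec.kind == "parallel_ribbon":
        cn = cn_parameter(end_to_end_units(frame, topology, members))
        if not np.isclose(cn, 1.0, atol=1e-12):
            raise AssertionError(f"parallel ribbon must have C_n = 1, got {cn}")
    elif spec.kind == "antiparallel_pair":
        u = end_to_end_units(frame, topology, members)
        if not np.isclose(u[0] @ u[1], -1.0, atol=1e-12):
            raise AssertionError("antiparallel pair must have opposite end-to-end vectors")
    elif spec.kind == "annular_ring":
        # every chain within the cluster cutoff of both ring neighbours
        assignment = find_clusters(frame, topology, DEFAULT_CUTOFF)
        if assignment.n_clusters != 1:
            raise AssertionError("annular ring must form a single cluster")
        n = spec.n_chains
        for k in range(n):
            for nb in ((k + 1) % n, (k - 1) % n):
                d = _min_interchain_distance(frame, topology, k, nb)
                if d > DEFAULT_CUTOFF:
                    raise AssertionError(
                        f"ring neighbours {k}, {nb} at {d:.3f} nm > cutoff")
    elif spec.kind == "amorphous_blob":
        centers = np.array([frame.positions[topology.chain_indices(c)].mean(axis=0)
                            for c in range(spec.n_chains)])
        r = np.linalg.norm(centers - np.full(3, spec.box / 2.0), axis=1)
        if np.any(r > spec.radius + 1.0):
            raise AssertionError("blob chains escaped the declared sphere")


def _min_interchain_distance(frame: Frame, topology: Topology,
                             a: int, b: int) -> float:
    pa = frame.positions[topology.chain_indices(a)]
    pb = frame.positions[topology.chain_indices(b)]
    d = minimum_image(pa[:, None, :] - pb[None, :, :], frame.box)
    return float(np.sqrt((d ** 2).sum(axis=2).min()))
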