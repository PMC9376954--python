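"""Langevin (stochastic) dynamics, energy minimization, and system setup.

The integrator is a BAOAB-splitting Langevin leapfrog: two half kicks (B)
and two half drifts (A) around an exact Ornstein-Uhlenbeck velocity update
(O).  The friction is specified GROMACS-style through the inverse friction
coefficient tau (a time constant), with per-bead friction gamma = m / tau
and the fluctuation-dissipation-matched noise

    v <- a v + sqrt((1 - a^2) kB T / m) xi,   a = exp(-dt / tau).

Limits behave as expected: tau -> infinity recovers symplectic velocity
Verlet (energy-conserving); T = 0 turns the noise off and velocities decay
geometrically; with all interactions off the O step alone samples the
Maxwell-Boltzmann distribution exactly, so the ideal-gas kinetic
temperature is unbiased at any time step.

Protocol defaults: dt = 15 fs, T = 303 K, tau = 0.17 ps, cubic periodic
box L = 35 nm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import KB, ForceField
from .system import Frame, InteractionTables, Trajectory, system_energy_forces
from .topology import Topology

logger = logging.getLogger(__name__)

#: Minimum distance (nm) between beads of different chains at insertion.
INSERTION_FLOOR = 0.5


@dataclass
class DynamicsSettings:
    """Integration protocol.  Defaults reproduce the reference protocol."""

    dt_fs: float = 15.0          # integration time step, fs
    temperature: float = 303.0   # thermostat temperature, K
    tau_ps: float = 0.17         # inverse friction coefficient, ps
    seed: int = 0
    n_steps: int = 1000
    sample_interval: int = 100   # steps between stored frames
    box: float = 35.0            # cubic box edge, nm

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.tau_ps <= 0:
            raise ValueError("tau must be positive")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3


# ---------------------------------------------------------------------------
# chain geometry and placement
# ---------------------------------------------------------------------------

def chain_template(n_residues: int, ff: ForceField) -> np.ndarray:
    """Straight-chain coordinates at the exact bonded-energy minimum.

    The backbone is a planar zigzag with 0.35 nm bonds whose directions
    alternate +/-15 deg about +x, giving every BBB angle exactly 150 deg.
    Each side-chain bead sits on the in-plane external bisector of its
    backbone vertex at distance r0_BS; because 105 = (360 - 150) / 2, this
    makes both of its BBS angles exactly 105 deg.  Caps extend the zigzag
    pattern with 0.35 nm BT bonds.  Bead order matches
    :func:`twobead.topology.build_topology`.
    """
    r_bb = ff.bonds["BB"].r0
    r_bt = ff.bonds["BT"].r0
    r_bs = ff.bonds["BS"].r0
    half = math.radians(15.0)  # half the 30 deg turn between bond directions

    # backbone bond directions alternate +/- 15 deg about x
    def bond_dir(k: int) -> np.ndarray:
        s = 1.0 if k % 2 == 0 else -1.0
        return np.array([math.cos(half), s * math.sin(half), 0.0])

    b = np.zeros((n_residues, 3))
    for r in range(1, n_residues):
        b[r] = b[r - 1] + r_bb * bond_dir(r - 1)

    coords = np.zeros((2 * n_residues + 2, 3))
    # TN extends the zigzag backwards along the virtual incoming bond
    coords[0] = b[0] - r_bt * bond_dir(-1)
    for r in range(n_residues):
        bi = 1 + 2 * r
        coords[bi] = b[r]
        # external bisector of the (virtual) incoming and outgoing directions
        u = bond_dir(r - 1)   # incoming direction at vertex r
        w = bond_dir(r)       # outgoing direction
        s = (u - w)
        s /= np.linalg.norm(s)
        coords[bi + 1] = b[r] + r_bs * s
    coords[-1] = b[-1] + r_bt * bond_dir(n_residues - 1)
    return coords


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def place_monomers(n_chains: int, n_residues: int, L: float, seed: int,
                   ff: ForceField | None = None,
                   min_distance: float = INSERTION_FLOOR,
                   max_attempts_per_chain: int = 2000) -> Frame:
    """Insert straight chains at random positions and orientations.

    No two beads of different chains end up closer (minimum image) than
    ``min_distance``.  Raises if the requested density cannot be realized
    within the retry budget.
    """
    from .forcefield import default_forcefield
    if ff is None:
        ff = default_forcefield()
    rng = np.random.default_rng(seed)
    template = chain_template(n_residues, ff)
    template = template - template.mean(axis=0)
    per_chain = len(template)

    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    for c in range(n_chains):
        ok = False
        for _ in range(max_attempts_per_chain):
            rot = random_rotation(rng)
            origin = rng.uniform(0.0, L, size=3)
            cand = template @ rot.T + origin
            if tree is None:
                ok = True
            else:
                dist, _ = tree.query(np.mod(cand, L), k=1,
                                     distance_upper_bound=min_distance)
                ok = bool(np.all(np.isinf(dist)))
            if ok:
                placed.append(cand)
                tree = cKDTree(np.mod(np.concatenate(placed), L), boxsize=L)
                break
        if not ok:
            raise RuntimeError(
                f"could not insert chain {c + 1}/{n_chains}: density too high "
                f"({n_chains} chains of {per_chain} beads, floor {min_distance} nm, "
                f"box {L} nm)")
    return Frame(np.concatenate(placed), box=L, time=0.0)


def maxwell_boltzmann_velocities(topology: Topology, temperature: float,
                                 seed: int) -> np.ndarray:
    """Draw per-bead velocities (nm/ps) from the MB distribution at T."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature / topology.masses)
    return rng.normal(size=(topology.n_beads, 3)) * sigma[:, None]


def instantaneous_temperature(frame: Frame, topology: Topology) -> float:
    """Kinetic temperature 2 KE / (3 n kB), in kelvin."""
    if frame.velocities is None:
        raise ValueError("frame carries no velocities")
    m = topology.masses
    ke = 0.5 * float(np.sum(m[:, None] * frame.velocities ** 2))
    return 2.0 * ke / (3.0 * topology.n_beads * KB)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def run_dynamics(frame: Frame, topology: Topology, ff: ForceField,
                 settings: DynamicsSettings, mode: str = "full") -> Trajectory:
    """Propagate Langevin dynamics; returns sampled frames (incl. t = 0).

    Velocities are taken from the input frame if present, otherwise drawn
    from the Maxwell-Boltzmann distribution at the run temperature using a
    seed stream separate from the thermostat noise.  Deterministic for a
    given (frame, settings) pair.  ``mode`` is forwarded to the energy
    evaluation ("full", "bonded_only", "nonbonded_only", or "none" for free
    beads).
    """
    ss = np.random.SeedSequence(settings.seed)
    noise_seed, vel_seed = ss.spawn(2)
    rng = np.random.default_rng(noise_seed)

    pos = frame.positions.copy()
    if frame.velocities is not None:
        vel = frame.velocities.copy()
    else:
        vel = maxwell_boltzmann_velocities(topology, settings.temperature,
                                           int(vel_seed.generate_state(1)[0] % 2**31))
    dt = settings.dt_ps
    m = topology.masses[:, None]
    a = math.exp(-dt / settings.tau_ps) if math.isfinite(settings.tau_ps) else 1.0
    noise_scale = np.sqrt((1.0 - a * a) * KB * settings.temperature / m)

    tables = InteractionTables(topology, ff)

    def force(p):
        if mode == "none":
            return np.zeros_like(p)
        _, f = system_energy_forces(Frame(p, frame.box, 0.0), topology, ff,
                                    tables, mode=mode)
        return f

    f = force(pos)
    t0 = frame.time
    traj = Trajectory(metadata={"settings": settings, "mode": mode})
    traj.frames.append(Frame(pos.copy(), frame.box, t0, vel.copy()))

    for step in range(1, settings.n_steps + 1):
        vel += 0.5 * dt * f / m                       # B
        pos += 0.5 * dt * vel                         # A
        vel *= a                                      # O
        if settings.temperature > 0 and a < 1.0:
            vel += noise_scale * rng.standard_normal(pos.shape)
        pos += 0.5 * dt * vel                         # A
        f = force(pos)
        vel += 0.5 * dt * f / m                       # B
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError(
                f"non-finite coordinates at step {step} (t = {t0 + step * dt * 1e-3:g} ns)")
        if step % settings.sample_interval == 0:
            traj.frames.append(Frame(pos.copy(), frame.box,
                                     t0 + step * dt * 1e-3, vel.copy()))
    return traj


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

@dataclass
class MinimizeResult:
    frame: Frame
    converged: bool
    n_iter: int
    energy: float
    max_force: float


def minimize(frame: Frame, topology: Topology, ff: ForceField,
             mode: str = "full", tol: float = 1.0,
             max_iter: int = 200_000) -> MinimizeResult:
    """Steepest-descent minimization with Barzilai-Borwein step control.

    Descends along the force until the largest force component drops below
    ``tol`` (kJ/mol/nm).  Steps that would raise the energy are rejected and
    the step size backtracked, so the energy is non-increasing across
    accepted steps.  ``mode="bonded_only"`` ignores all nonbonded terms.
    """
    tables = InteractionTables(topology, ff)

    def ef(p):
        terms, f = system_energy_forces(Frame(p, frame.box, 0.0), topology,
                                        ff, tables, mode=mode)
        return terms["total"], f

    pos = frame.positions.copy()
    e, f = ef(pos)
    gamma = 1e-4  # initial step, nm^2 mol / kJ
    prev_pos = None
    prev_f = None
    it = 0
    for it in range(1, max_iter + 1):
        fmax = float(np.abs(f).max())
        if fmax < tol:
            break
        if prev_pos is not None:
            ds = (pos - prev_pos).ravel()
            dg = (prev_f - f).ravel()  # gradient difference = -(f - f_prev)
            denom = float(ds @ dg)
            if denom > 0:
                gamma = float(ds @ ds) / denom
            else:
                gamma = 1e-4
        accepted = False
        for _ in range(40):
            cand = pos + gamma * f
            e_new, f_new = ef(cand)
            if e_new <= e:
                prev_pos, prev_f = pos, f
                pos, e, f = cand, e_new, f_new
                accepted = True
                break
            gamma *= 0.5
        if not accepted:
            break
    fmax = float(np.abs(f).max())
    converged = fmax < tol
    if not converged:
        logger.warning("minimization did not converge: max |F| = %.3g after %d iters",
                       fmax, it)
    out = Frame(pos, frame.box, frame.time, None)
    return MinimizeResult(frame=out, converged=converged, n_iter=it,
                          energy=e, max_force=fmax)
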