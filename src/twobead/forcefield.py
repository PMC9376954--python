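"""Force-field parameters and potential-energy terms of the two-bead peptide model.

The model represents an n-residue peptide by 2n + 2 spherical interaction
sites ("superatoms" or beads): one backbone bead (B) and one side-chain bead
(S) per residue, plus an N-terminal cap (TN) and a C-terminal cap (TC).
Bonded terms are harmonic bonds and cosine-harmonic angles; nonbonded terms
are Lennard-Jones pair potentials, with a purely repulsive variant for
identical-terminus pairs that mimics the electrostatic repulsion of
like-charged chain ends.

Two parameters are deliberately tunable ("scanned"): the side-chain LJ
radius ``sigma_SS`` (physical range 0.37-0.45 nm) and the equilibrium
backbone/side-chain bond length ``r0_BS`` (0.40-0.70 nm).  Together they set
the side-chain geometry that controls whether aggregates come out amorphous,
glassy, fibrillar or annular.

Units follow the GROMACS convention throughout: nm, kJ/mol, amu, ps.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.008314462618

#: Bead mass in amu.  The model does not prescribe masses (overdamped
#: aggregation behaviour is mass-insensitive); the uniform MARTINI bead
#: mass is used for every superatom.
DEFAULT_BEAD_MASS = 72.0

#: Scanned-parameter ranges explored in the phase diagram.
SIGMA_SS_RANGE = (0.37, 0.45)
R0_BS_RANGE = (0.40, 0.70)

#: Default nonbonded cutoff (nm).  Potentials are shifted to zero at the
#: cutoff so the energy is continuous.
DEFAULT_CUTOFF = 1.2

#: Pair distance (nm) below which a configuration is flagged as overlapping.
OVERLAP_FLOOR = 0.05


class BeadKind(str, enum.Enum):
    """The four superatom kinds.

    TN and TC share bonded parameters (a single BT bond class) but are
    distinct nonbonded identities: opposite termini attract strongly while
    identical termini are purely repulsive, mimicking zwitterionic capping.
    """

    B = "B"    # backbone
    S = "S"    # side chain
    TN = "TN"  # N-terminal cap
    TC = "TC"  # C-terminal cap


def _pairkey(a: BeadKind, b: BeadKind) -> tuple[str, str]:
    """Unordered bead-kind pair key."""
    return tuple(sorted((BeadKind(a).value, BeadKind(b).value)))  # type: ignore[return-value]


@dataclass(frozen=True)
class BondParams:
    k_b: float   # kJ mol^-1 nm^-2
    r0: float    # nm


@dataclass(frozen=True)
class AngleParams:
    k_theta: float  # kJ mol^-1
    theta0: float   # degrees


@dataclass(frozen=True)
class PairParams:
    sigma: float           # nm
    epsilon: float         # kJ mol^-1
    repulsive_only: bool = False


@dataclass
class ForceField:
    """Complete parameter set: bond, angle and nonbonded pair tables.

    ``bonds`` is keyed by bond class ("BB", "BT", "BS"); ``angles`` by angle
    class ("BBB", "BBS"); ``pairs`` by unordered (kind, kind) tuples.
    ``sigma_SS`` and ``r0_BS`` record the scanned parameters the tables were
    built from.
    """

    bonds: dict[str, BondParams]
    angles: dict[str, AngleParams]
    pairs: dict[tuple[str, str], PairParams]
    sigma_SS: float
    r0_BS: float
    cutoff: float = DEFAULT_CUTOFF
    shift_at_cutoff: bool = True
    angle_form: str = "cosine"          # "cosine" | "harmonic"
    repulsive_form: str = "r12"         # "r12" | "wca"
    sigma_combination: str = "arithmetic"

    def pair_params(self, a: BeadKind, b: BeadKind) -> PairParams:
        return self.pairs[_pairkey(a, b)]

    def with_options(self, **kw) -> "ForceField":
        return replace(self, **kw)


def combine_sigma(sigma_a: float, sigma_b: float, rule: str = "arithmetic") -> float:
    """Lorentz-style combination for the cross LJ radius.

    The backbone/side-chain radius sigma_BS follows from sigma_BB and
    sigma_SS by the arithmetic mean (the standard Lorentz rule); a geometric
    alternative is kept for sensitivity checks.
    """
    if rule == "arithmetic":
        return 0.5 * (sigma_a + sigma_b)
    if rule == "geometric":
        return math.sqrt(sigma_a * sigma_b)
    raise ValueError(f"unknown sigma combination rule: {rule!r}")


def default_forcefield(sigma_SS: float = 0.41, r0_BS: float = 0.55, *,
                       sigma_combination: str = "arithmetic",
                       cutoff: float = DEFAULT_CUTOFF) -> ForceField:
    """Build the full parameter set for given scanned parameters.

    Parameters
    ----------
    sigma_SS
        Side-chain LJ radius in nm.  The phase diagram scans 0.37-0.45 nm;
        values outside that window are accepted but logged.
    r0_BS
        Equilibrium backbone/side-chain bond length in nm (scan: 0.40-0.70).

    All other constants are fixed: backbone and terminal bonds
    k_b = 1250 kJ/mol/nm^2 at r0 = 0.35 nm, the stiff side-chain bond
    k_b = 5000 kJ/mol/nm^2, angle constants k_theta = 1000 kJ/mol with
    equilibrium angles 150 deg (BBB) and 105 deg (BBS), and the LJ pair
    matrix with a strong backbone-backbone attraction (epsilon_BB = 4.5
    kJ/mol), intermediate backbone/side-chain (2.0) and weak side-chain
    (1.0) attractions, weakly interacting termini (0.5) except the strong
    opposite-terminus attraction (4.0) and the purely repulsive
    identical-terminus pairs (4.0, repulsive_only).
    """
    if sigma_SS <= 0 or r0_BS <= 0:
        raise ValueError(
            f"scan parameters must be positive: sigma_SS={sigma_SS}, r0_BS={r0_BS}")
    if not (SIGMA_SS_RANGE[0] <= sigma_SS <= SIGMA_SS_RANGE[1]):
        logger.warning("sigma_SS=%g nm outside the scanned range %s", sigma_SS, SIGMA_SS_RANGE)
    if not (R0_BS_RANGE[0] <= r0_BS <= R0_BS_RANGE[1]):
        logger.warning("r0_BS=%g nm outside the scanned range %s", r0_BS, R0_BS_RANGE)

    sigma_BB = 0.47
    sigma_BS = combine_sigma(sigma_BB, sigma_SS, sigma_combination)

    bonds = {
        "BB": BondParams(k_b=1250.0, r0=0.35),
        "BT": BondParams(k_b=1250.0, r0=0.35),
        "BS": BondParams(k_b=5000.0, r0=r0_BS),
    }
    angles = {
        "BBB": AngleParams(k_theta=1000.0, theta0=150.0),
        "BBS": AngleParams(k_theta=1000.0, theta0=105.0),
    }

    B, S, TN, TC = BeadKind.B, BeadKind.S, BeadKind.TN, BeadKind.TC
    pairs: dict[tuple[str, str], PairParams] = {}

    def put(a, b, sigma, epsilon, rep=False):
        pairs[_pairkey(a, b)] = PairParams(sigma=sigma, epsilon=epsilon, repulsive_only=rep)

    put(B, B, sigma_BB, 4.5)
    put(B, S, sigma_BS, 2.0)
    put(S, S, sigma_SS, 1.0)
    # termini: sigma 0.40 for every pair involving a cap
    for t in (TN, TC):
        put(B, t, 0.40, 0.5)
        put(S, t, 0.40, 0.5)
    put(TN, TC, 0.40, 4.0)            # opposite termini attract
    put(TN, TN, 0.40, 4.0, rep=True)  # identical termini repel
    put(TC, TC, 0.40, 4.0, rep=True)

    return ForceField(bonds=bonds, angles=angles, pairs=pairs,
                      sigma_SS=sigma_SS, r0_BS=r0_BS, cutoff=cutoff,
                      sigma_combination=sigma_combination)


# ---------------------------------------------------------------------------
# scalar potential forms (raw, untruncated; used directly in unit tests and
# as the building blocks of the vectorized system energy)
# ---------------------------------------------------------------------------

def bond_energy(r: float, k_b: float, r0: float) -> float:
    """Harmonic bond: V = (1/2) k_b (r - r0)^2."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    return 0.5 * k_b * (r - r0) ** 2


def angle_energy(theta: float, k_theta: float, theta0: float,
                 form: str = "cosine") -> float:
    """Bending energy for an angle given in degrees.

    The default is the cosine-harmonic form V = (1/2) k (cos t - cos t0)^2
    (the MARTINI convention, consistent with k quoted in kJ/mol); a
    harmonic-in-angle alternative is selectable.
    """
    if not (0.0 <= theta <= 180.0):
        raise ValueError("theta must lie in [0, 180] degrees")
    if form == "cosine":
        return 0.5 * k_theta * (math.cos(math.radians(theta))
                                - math.cos(math.radians(theta0))) ** 2
    if form == "harmonic":
        return 0.5 * k_theta * (math.radians(theta) - math.radians(theta0)) ** 2
    raise ValueError(f"unknown angle form: {form!r}")


def lj_pair_energy(r: float, sigma: float, epsilon: float) -> float:
    """Raw 12-6 Lennard-Jones: V = 4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def replj_pair_energy(r: float, sigma: float, epsilon: float,
                      form: str = "r12") -> float:
    """Purely repulsive pair potential for identical termini.

    Default is the repulsion-only LJ term V = 4 eps (sigma/r)^12 (an LJ with
    the attractive coefficient zeroed); a WCA form (LJ cut and shifted at the
    minimum) is selectable.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if form == "r12":
        return 4.0 * epsilon * (sigma / r) ** 12
    if form == "wca":
        rmin = 2.0 ** (1.0 / 6.0) * sigma
        if r >= rmin:
            return 0.0
        return lj_pair_energy(r, sigma, epsilon) + epsilon
    raise ValueError(f"unknown repulsive form: {form!r}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def forcefield_to_kv(ff: ForceField) -> str:
    """Serialize a force field to a flat key=value text block."""
    lines = ["# twobead force-field parameter file"]
    for opt in ("sigma_SS", "r0_BS", "cutoff", "shift_at_cutoff", "angle_form",
                "repulsive_form", "sigma_combination"):
        lines.append(f"{opt} = {getattr(ff, opt)}")
    for cls, bp in sorted(ff.bonds.items()):
        lines.append(f"bond.{cls}.k_b = {bp.k_b}")
        lines.append(f"bond.{cls}.r0 = {bp.r0}")
    for cls, ap in sorted(ff.angles.items()):
        lines.append(f"angle.{cls}.k_theta = {ap.k_theta}")
        lines.append(f"angle.{cls}.theta0 = {ap.theta0}")
    for (a, b), pp in sorted(ff.pairs.items()):
        key = f"pair.{a}-{b}"
        lines.append(f"{key}.sigma = {pp.sigma}")
        lines.append(f"{key}.epsilon = {pp.epsilon}")
        lines.append(f"{key}.repulsive_only = {pp.repulsive_only}")
    return "\n".join(lines) + "\n"


def forcefield_from_kv(text: str) -> ForceField:
    """Parse a force field from the flat key=value format."""
    kv: dict[str, str] = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line {ln}: {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v

    def fget(key):
        return float(kv.pop(key))

    def bget(key):
        return kv.pop(key) == "True"

    bonds = {}
    angles = {}
    pairs = {}
    for key in list(kv):
        parts = key.split(".")
        if parts[0] == "bond":
            cls = parts[1]
            if cls not in bonds:
                bonds[cls] = BondParams(k_b=fget(f"bond.{cls}.k_b"),
                                        r0=fget(f"bond.{cls}.r0"))
        elif parts[0] == "angle":
            cls = parts[1]
            if cls not in angles:
                angles[cls] = AngleParams(k_theta=fget(f"angle.{cls}.k_theta"),
                                          theta0=fget(f"angle.{cls}.theta0"))
        elif parts[0] == "pair":
            a, b = parts[1].split("-")
            if (a, b) not in pairs:
                pairs[(a, b)] = PairParams(
                    sigma=fget(f"pair.{a}-{b}.sigma"),
                    epsilon=fget(f"pair.{a}-{b}.epsilon"),
                    repulsive_only=bget(f"pair.{a}-{b}.repulsive_only"))
    return ForceField(
        bonds=bonds, angles=angles, pairs=pairs,
        sigma_SS=fget("sigma_SS"), r0_BS=fget("r0_BS"), cutoff=fget("cutoff"),
        shift_at_cutoff=bget("shift_at_cutoff"),
        angle_form=kv.pop("angle_form"),
        repulsive_form=kv.pop("repulsive_form"),
        sigma_combination=kv.pop("sigma_combination"),
    )


def write_itp(ff: ForceField, topology, path) -> None:
    """Convenience export of one chain's topology in a GROMACS .itp dialect.

    Intended for cross-checking parameters in external tools; not a
    round-trip format.  Nonbonded pair types go into a commented
    [ nonbond_params ]-style block using C6/C12 coefficients.
    """
    from .topology import bond_class, angle_class  # local import, no cycle at module load

    lines = ["; twobead convenience export -- for cross-checking only",
             "[ moleculetype ]", "; name  nrexcl", "PEP  1", "", "[ atoms ]"]
    for b in topology.beads:
        lines.append(f"{b.index + 1:6d}  {b.kind.value:4s} {b.residue + 1:5d}  PEP  "
                     f"{b.kind.value:4s} {b.index + 1:6d}  0.000  {b.mass:.3f}")
    lines += ["", "[ bonds ]"]
    for (i, j), cls in zip(topology.bond_pairs, topology.bond_classes):
        bp = ff.bonds[cls]
        lines.append(f"{i + 1:6d} {j + 1:6d}  1  {bp.r0:.4f}  {bp.k_b:.1f}")
    lines += ["", "[ angles ]"]
    for (i, j, k), cls in zip(topology.angle_triplets, topology.angle_classes):
        ap = ff.angles[cls]
        lines.append(f"{i + 1:6d} {j + 1:6d} {k + 1:6d}  2  {ap.theta0:.2f}  {ap.k_theta:.1f}")
    lines += ["", "; [ nonbond_params ] (C6, C12)"]
    for (a, b), pp in sorted(ff.pairs.items()):
        c12 = 4.0 * pp.epsilon * pp.sigma ** 12
        c6 = 0.0 if pp.repulsive_only else 4.0 * pp.epsilon * pp.sigma ** 6
        lines.append(f"; {a:3s} {b:3s}  {c6:.6e}  {c12:.6e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
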