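"""End-to-end and backbone-backbone order parameters, phase classification."""

import numpy as np
import pytest

from twobead import (FixtureSpec, Frame, OrderDescriptors, PhaseBoundaries,
                     Trajectory, aggregate_energy_series, backbone_centers,
                     build_topology, cbb_parameter, chain_template,
                     classify_phase, cn_parameter, describe_cluster,
                     end_to_end_units, make_fixture, system_energy)
from twobead.dynamics import random_rotation
from twobead.order import cbb_from_centers, unwrap_chain


def random_units(m, rng):
    v = rng.normal(size=(m, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestEndToEndUnits:
    def test_straight_chain_direction(self, ff, r8_topology, r8_frame):
        u = end_to_end_units(r8_frame, r8_topology, [0])
        bb = r8_topology.backbone_indices(0)
        v = r8_frame.positions[bb[-1]] - r8_frame.positions[bb[0]]
        assert u.shape == (1, 3)
        assert np.allclose(u[0], v / np.linalg.norm(v))
        # the zigzag runs predominantly along +x
        assert u[0, 0] > 0.99

    def test_rotated_copy_has_opposite_vector(self, ff):
        spec = FixtureSpec(kind="antiparallel_pair", n_chains=2)
        frame, top = make_fixture(spec, ff)
        u = end_to_end_units(frame, top, [0, 1])
        assert u[0] @ u[1] == pytest.approx(-1.0)

    def test_unit_norm(self, ff):
        frame, top = make_fixture(FixtureSpec(kind="random_gas", n_chains=20,
                                              seed=1), ff)
        u = end_to_end_units(frame, top, np.arange(20))
        assert np.allclose(np.linalg.norm(u, axis=1), 1.0)

    def test_degenerate_vector_rejected(self, ff):
        top = build_topology(2, 1)
        pos = chain_template(2, ff)
        bb = top.backbone_indices(0)
        pos[bb[-1]] = pos[bb[0]]  # collapse the backbone ends
        with pytest.raises(ValueError, match="peptide 0"):
            end_to_end_units(Frame(pos, 35.0), top, [0])


class TestCnParameter:
    def test_identical_vectors(self):
        u = np.tile([0.0, 0.0, 1.0], (10, 1))
        assert cn_parameter(u) == pytest.approx(1.0)

    def test_antiparallel_pair(self):
        u = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert cn_parameter(u) == pytest.approx(1.0)

    def test_mixed_parallel_antiparallel(self):
        u = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 0, 1.0], [0, 0, -1.0]])
        assert cn_parameter(u) == pytest.approx(1.0)

    def test_random_orientations_average_one_third(self):
        # E[(n.n')^2] = 1/3 for isotropic unit vectors
        rng = np.random.default_rng(2024)
        vals = [cn_parameter(random_units(72, rng)) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        u = random_units(15, rng)
        flipped = u.copy()
        flipped[::2] *= -1.0
        assert cn_parameter(flipped) == pytest.approx(cn_parameter(u))

    def test_orthogonal_pair(self):
        u = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        assert cn_parameter(u) == pytest.approx(0.0)

    def test_single_chain_undefined(self):
        assert np.isnan(cn_parameter(np.array([[1.0, 0, 0]])))


class TestBackboneCenters:
    def test_straight_chain_midpoint(self, ff, r8_topology, r8_frame):
        c = backbone_centers(r8_frame, r8_topology, [0])
        bb = r8_topology.backbone_indices(0)
        assert np.allclose(c[0], r8_frame.positions[bb].mean(axis=0))

    def test_translation_covariance(self, ff, r8_topology, r8_frame):
        c1 = backbone_centers(r8_frame, r8_topology, [0])
        moved = r8_frame.copy()
        moved.positions = moved.positions + np.array([1.0, 2.0, 3.0])
        c2 = backbone_centers(moved, r8_topology, [0])
        assert np.allclose(c2 - c1, [1.0, 2.0, 3.0])

    def test_chain_split_across_boundary(self, ff, r8_topology):
        # wrap a chain over the boundary: the centre must come from the
        # unwrapped image, matching an explicitly whole copy
        whole = Frame(chain_template(8, ff) + [34.0, 10.0, 10.0], box=35.0)
        split = whole.copy()
        split.positions = np.mod(split.positions, 35.0)
        c_whole = backbone_centers(whole, r8_topology, [0])
        c_split = backbone_centers(split, r8_topology, [0])
        d = (c_whole - c_split) - 35.0 * np.round((c_whole - c_split) / 35.0)
        assert np.allclose(d, 0.0, atol=1e-10)

    def test_unwrap_restores_bond_lengths(self, ff, r8_topology):
        split = Frame(np.mod(chain_template(8, ff) + [34.0, 10.0, 10.0], 35.0),
                      box=35.0)
        bb = r8_topology.backbone_indices(0)
        unwrapped = unwrap_chain(split, bb)
        bonds = np.linalg.norm(np.diff(unwrapped, axis=0), axis=1)
        assert np.allclose(bonds, 0.35, atol=1e-12)


class TestCbbParameter:
    def test_collinear_lattice(self):
        centers = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        val, n = cbb_from_centers(centers, box=35.0)
        assert val == pytest.approx(1.0)
        assert n == 4

    def test_orthogonal_neighbors(self):
        # only the corner peptide has two shell neighbours (the outer pair
        # sits beyond the shell), and they lie at right angles
        centers = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.4, 0]])
        val, n = cbb_from_centers(centers, box=35.0)
        assert val == pytest.approx(0.0, abs=1e-12)
        assert n == 1

    def test_matches_brute_force_oracle(self, ff):
        # independent double-loop implementation on a random shell gas
        rng = np.random.default_rng(9)
        centers = rng.uniform(10.0, 14.0, size=(12, 3))
        box = 35.0
        lo, hi = 0.8, 2.4
        vals = []
        for i in range(len(centers)):
            nbrs = []
            for j in range(len(centers)):
                if i == j:
                    continue
                d = centers[j] - centers[i]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d)
                if lo <= r <= hi:
                    nbrs.append(d / r)
            acc = []
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    acc.append(abs(nbrs[a] @ nbrs[b]))
            if acc:
                vals.append(np.mean(acc))
        expected = np.mean(vals)
        got, n = cbb_from_centers(centers, box)
        assert got == pytest.approx(expected, abs=1e-12)
        assert n == len(vals)

    def test_undefined_when_no_shell_pairs(self, ff):
        centers = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        val, n = cbb_from_centers(centers, box=35.0)
        assert np.isnan(val) and n == 0

    def test_fixture_pipeline(self, ff):
        frame, top = make_fixture(FixtureSpec(kind="parallel_ribbon",
                                              n_chains=10, spacing=1.0), ff)
        val, n = cbb_parameter(frame, top, np.arange(10))
        assert val == pytest.approx(1.0)


class TestRigidMotionInvariance:
    def test_descriptors_invariant_under_rotation_translation(self, ff):
        frame, top = make_fixture(FixtureSpec(kind="amorphous_blob",
                                              n_chains=12, radius=2.0,
                                              seed=5), ff)
        members = np.arange(12)
        d1 = describe_cluster(frame, top, members)
        rng = np.random.default_rng(10)
        R = random_rotation(rng)
        moved = frame.copy()
        center = np.full(3, frame.box / 2.0)
        moved.positions = (frame.positions - center) @ R.T + center + [1.0, -2.0, 0.5]
        d2 = describe_cluster(moved, top, members)
        assert d2.c_n == pytest.approx(d1.c_n, abs=1e-10)
        assert d2.c_bb == pytest.approx(d1.c_bb, abs=1e-10)

    def test_fibril_scores_above_random_gas(self, ff):
        ribbon, top_r = make_fixture(FixtureSpec(kind="parallel_ribbon",
                                                 n_chains=12, spacing=1.0), ff)
        gas, top_g = make_fixture(FixtureSpec(kind="random_gas", n_chains=12,
                                              box=6.0, seed=6), ff)
        d_rib = describe_cluster(ribbon, top_r, np.arange(12))
        d_gas = describe_cluster(gas, top_g, np.arange(12))
        assert d_rib.c_n > d_gas.c_n
        assert np.isnan(d_gas.c_bb) or d_rib.c_bb > d_gas.c_bb


class TestPhaseClassification:
    @pytest.mark.parametrize("cn,cbb,label", [
        (1.0, 1.0, "single-ribbon"),
        (0.95, 0.65, "multi-ribbon/annular"),
        (0.5, 0.45, "amyloid-glass"),
        (0.33, 0.2, "amorphous"),
        (0.2, 0.85, "single-ribbon"),   # C_BB dominates
    ])
    def test_region_lookup(self, cn, cbb, label):
        d = OrderDescriptors(c_n=cn, c_bb=cbb, cluster_size=72)
        assert classify_phase(d) == label

    def test_random_fixture_classified_amorphous(self, ff):
        rng = np.random.default_rng(11)
        cn = cn_parameter(random_units(72, rng))
        d = OrderDescriptors(c_n=cn, c_bb=0.3, cluster_size=72)
        assert classify_phase(d) == "amorphous"

    def test_undefined_descriptors(self):
        d = OrderDescriptors(c_n=float("nan"), c_bb=0.5, cluster_size=1)
        assert classify_phase(d) == "unclassified"

    def test_boundaries_configurable(self):
        d = OrderDescriptors(c_n=0.7, c_bb=0.7, cluster_size=10)
        assert classify_phase(d) == "multi-ribbon/annular"
        tight = PhaseBoundaries(cbb_single=0.65)
        assert classify_phase(d, tight) == "single-ribbon"


class TestAggregateEnergy:
    def test_static_frame_zero_spread(self, ff, r8_topology, r8_frame):
        traj = Trajectory(frames=[r8_frame.copy() for _ in range(5)])
        mean, sd, _ = aggregate_energy_series(traj, r8_topology, ff)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(system_energy(r8_frame, r8_topology, ff))

    def test_single_frame_window(self, ff, r8_topology, r8_frame, perturbed_r8):
        traj = Trajectory(frames=[r8_frame, perturbed_r8])
        mean, sd, es = aggregate_energy_series(traj, r8_topology, ff,
                                               window=slice(1, 2))
        assert len(es) == 1
        assert mean == pytest.approx(system_energy(perturbed_r8, r8_topology, ff))

    def test_minimized_bonded_chain_energy_bookkeeping(self, ff, r8_topology,
                                                       r8_frame):
        from twobead import system_energy_forces
        terms, _ = system_energy_forces(r8_frame, r8_topology, ff)
        assert terms["bond"] + terms["angle"] == pytest.approx(0.0, abs=1e-18)
        assert terms["total"] == pytest.approx(terms["lj"] + terms["replj"])

    def test_empty_window_rejected(self, ff, r8_topology, r8_frame):
        traj = Trajectory(frames=[r8_frame])
        with pytest.raises(ValueError):
            aggregate_energy_series(traj, r8_topology, ff, window=slice(5, 5))
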