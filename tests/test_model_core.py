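"""Potentials, forces, and configuration contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syxsim.model_core import (
    SimulationConfig,
    SystemState,
    attraction_potential,
    membrane_potential,
    pairwise_energy_and_forces,
    repulsion_potential,
)


def finite_difference_force(u_func, d, h=1e-6):
    """Central-difference -dU/dd, the oracle for every analytic force."""
    up, _ = u_func(d + h)
    um, _ = u_func(d - h)
    return -(up - um) / (2.0 * h)


class TestMembranePotential:
    def test_minimum_at_plane(self):
        u, f = membrane_potential(0.0, 20.0)
        assert u == 0.0 and f == 0.0

    def test_printed_value(self):
        u, _ = membrane_potential(1.0, 20.0)
        assert u == pytest.approx(10.0)

    def test_force_is_gradient(self):
        f_num = finite_difference_force(lambda d: membrane_potential(d, 20.0), 0.5)
        _, f = membrane_potential(0.5, 20.0)
        assert f == pytest.approx(f_num, rel=1e-6)

    def test_rejects_nonpositive_stiffness(self):
        with pytest.raises(ValueError):
            membrane_potential(1.0, 0.0)


class TestRepulsionPotential:
    @pytest.mark.parametrize("d, expected", [
        (6.6, 0.0),        # contact
        (7.6, 0.0),        # beyond contact
        (5.6, 1.0),        # 1 nm overlap at k = 2
    ])
    def test_piecewise_values(self, d, expected):
        u, _ = repulsion_potential(d, 6.6, 2.0)
        assert u == pytest.approx(expected)

    def test_force_zero_at_and_beyond_contact(self):
        for d in (6.6, 8.0):
            _, f = repulsion_potential(d, 6.6, 2.0)
            assert f == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            repulsion_potential(-0.1, 6.6, 2.0)


class TestAttractionPotential:
    R_SUM, I_RAD, EA = 6.0, 8.25, 4.0

    def u(self, d):
        return attraction_potential(d, self.R_SUM, self.I_RAD, self.EA)

    def test_well_depth_at_contact(self):
        u, _ = self.u(self.R_SUM)
        assert u == pytest.approx(-self.EA)

    def test_vanishes_at_cutoff(self):
        u, f = self.u(self.I_RAD)
        assert u == 0.0 and f == 0.0

    def test_midpoint_value_from_both_branches(self):
        # both adjacent branch formulas, evaluated independently, give
        # -E_a/2 at the midpoint (r_sum 6.0, i 8.25, E_a 4.0 -> -2.0)
        r, i, ea = self.R_SUM, self.I_RAD, self.EA
        mid = 0.5 * (i + r)
        left = 2 * ea / (i - r) ** 2 * (mid - r) ** 2 - ea
        right = -2 * ea / (i - r) ** 2 * (mid - i) ** 2
        assert left == pytest.approx(-2.0)
        assert right == pytest.approx(-2.0)
        u, _ = self.u(mid)
        assert u == pytest.approx(-2.0)

    def test_c0_c1_continuity_on_dense_grid(self):
        # the three interior branch boundaries must join without jumps
        # in either the energy or the force
        d = np.linspace(0.1, self.I_RAD + 1.0, 200_001)
        u, f = self.u(d)
        du = np.abs(np.diff(u))
        df = np.abs(np.diff(f))
        h = d[1] - d[0]
        max_slope = self.EA  # steepest branch stiffness ~ k_core
        assert du.max() < 10 * max_slope * h + 1e-8
        assert df.max() < 10 * max_slope * h + 1e-8

    def test_force_matches_finite_difference_everywhere(self):
        for d in [4.0, 5.9, 6.1, 7.0, 7.2, 8.0]:
            _, f = self.u(d)
            assert f == pytest.approx(finite_difference_force(self.u, d), rel=1e-5, abs=1e-8)

    def test_zero_beyond_cutoff(self):
        u, f = self.u(10.0)
        assert u == 0.0 and f == 0.0

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            attraction_potential(6.0, 6.0, 5.0, 4.0)


class TestPotentialProperties:
    """Invariants that must hold for arbitrary admissible parameters."""

    @settings(derandomize=True, max_examples=200)
    @given(d=st.floats(0.0, 30.0), r_sum=st.floats(0.5, 10.0),
           k=st.floats(0.1, 50.0))
    def test_repulsion_vanishes_at_and_beyond_contact(self, d, r_sum, k):
        u, f = repulsion_potential(d, r_sum, k)
        assert u >= 0.0
        if d >= r_sum:
            assert u == 0.0 and f == 0.0
        else:
            assert f > 0.0  # always pushes apart

    @settings(derandomize=True, max_examples=200)
    @given(d=st.floats(0.01, 30.0), r_sum=st.floats(0.5, 10.0),
           gap=st.floats(0.1, 10.0), e_a=st.floats(0.0, 10.0))
    def test_attraction_bounded_by_well_depth_and_compact(self, d, r_sum,
                                                          gap, e_a):
        i_rad = r_sum + gap
        u, f = attraction_potential(d, r_sum, i_rad, e_a)
        assert u >= -e_a - 1e-12  # -E_a is the global minimum
        if d >= i_rad:
            assert u == 0.0 and f == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(d=st.floats(0.05, 29.0), r_sum=st.floats(0.5, 10.0),
           gap=st.floats(0.1, 10.0), e_a=st.floats(0.01, 10.0))
    def test_attraction_force_is_negative_gradient(self, d, r_sum, gap, e_a):
        i_rad = r_sum + gap
        h = 1e-6
        # skip points within h of a branch boundary, where the
        # central difference straddles two formulas
        for boundary in (r_sum, 0.5 * (r_sum + i_rad), i_rad):
            if abs(d - boundary) < 10 * h:
                return
        up, _ = attraction_potential(d + h, r_sum, i_rad, e_a)
        um, _ = attraction_potential(d - h, r_sum, i_rad, e_a)
        _, f = attraction_potential(d, r_sum, i_rad, e_a)
        assert f == pytest.approx(-(up - um) / (2 * h), rel=1e-3, abs=1e-6)


class TestConfig:
    def test_defaults_are_reference_conditions(self):
        cfg = SimulationConfig()
        assert cfg.n_molecules == 500
        assert cfg.domain_radius == 300.0
        assert (cfg.r1, cfg.r2) == (3.0, 3.3)
        assert cfg.i_radius == pytest.approx(8.25)
        assert cfg.dt == 5.0
        assert cfg.d_eff_sim == pytest.approx(2e-4)

    def test_size_ratio_warning(self):
        with pytest.warns(UserWarning, match="unbounded"):
            SimulationConfig(r1=3.0, r2=3.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            SimulationConfig.from_dict({"n_molecules": 10, "bogus": 1})

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yml"
        p.write_text("n_molecules: 7\ndomain_radius: 100.0\ne_a: 4.4\n")
        cfg = SimulationConfig.from_yaml(p)
        assert cfg.n_molecules == 7 and cfg.e_a == 4.4

    @pytest.mark.parametrize("bad", [
        {"e_a": -1.0}, {"dt": 0.0}, {"domain_radius": 20.0},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


def random_state(n, rng, spread=30.0):
    pos1 = np.zeros((n, 3))
    pos1[:, :2] = rng.uniform(-spread, spread, (n, 2))
    pos1[:, 2] = rng.normal(0, 0.2, n)
    pos2 = pos1 + rng.normal(0, 0.5, (n, 3))
    pos2[:, 2] += 6.3
    return SystemState(time=0.0, pos1=pos1, pos2=pos2,
                       mobile=np.ones(n, dtype=bool), e_a=np.full(n, 4.0))


class TestPairwiseForces:
    def test_noninteracting_molecules_have_zero_pair_energy(self):
        cfg = SimulationConfig(n_molecules=2, domain_radius=100.0)
        pos1 = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        pos2 = pos1 + [0.0, 0.0, 6.3]
        st = SystemState(0.0, pos1, pos2, np.ones(2, bool), np.full(2, 4.0))
        e, f1, f2 = pairwise_energy_and_forces(st, cfg)
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f1, 0.0, atol=1e-12)
        np.testing.assert_allclose(f2, 0.0, atol=1e-12)

    def test_forces_match_finite_difference_gradient(self):
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(n_molecules=5, domain_radius=100.0)
        st = random_state(5, rng, spread=8.0)
        e0, f1, f2 = pairwise_energy_and_forces(st, cfg)
        h = 1e-6
        for which in (0, 1):
            pos = st.pos1 if which == 0 else st.pos2
            ana = f1 if which == 0 else f2
            for i in range(5):
                for k in range(3):
                    stp = st.copy()
                    (stp.pos1 if which == 0 else stp.pos2)[i, k] += h
                    stm = st.copy()
                    (stm.pos1 if which == 0 else stm.pos2)[i, k] -= h
                    ep, _, _ = pairwise_energy_and_forces(stp, cfg)
                    em, _, _ = pairwise_energy_and_forces(stm, cfg)
                    num = -(ep - em) / (2 * h)
                    assert ana[i, k] == pytest.approx(num, rel=1e-5, abs=1e-5)

    def test_newtons_third_law_net_pair_force(self):
        # without external fields (wall, membrane, bond are
        # intramolecular or external), pair forces must sum to zero
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(n_molecules=6, domain_radius=100.0, k_m=1e-12)
        st = random_state(6, rng, spread=6.0)
        st.pos1[:, 2] = 0.0
        e, f1, f2 = pairwise_energy_and_forces(st, cfg, include_wall=False,
                                               include_bond=True)
        np.testing.assert_allclose((f1 + f2).sum(axis=0), 0.0, atol=1e-9)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(n_molecules=4, domain_radius=100.0)
        st = random_state(4, rng, spread=6.0)
        _, f1, f2 = pairwise_energy_and_forces(st, cfg)
        mirrored = st.copy()
        mirrored.pos1[:, 0] *= -1
        mirrored.pos2[:, 0] *= -1
        _, g1, g2 = pairwise_energy_and_forces(mirrored, cfg)
        np.testing.assert_allclose(g1[:, 0], -f1[:, 0], atol=1e-10)
        np.testing.assert_allclose(g1[:, 1:], f1[:, 1:], atol=1e-10)
        np.testing.assert_allclose(g2[:, 0], -f2[:, 0], atol=1e-10)

    def test_inplane_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        cfg = SimulationConfig(n_molecules=5, domain_radius=100.0)
        st = random_state(5, rng, spread=6.0)
        e0, _, _ = pairwise_energy_and_forces(st, cfg, include_wall=False)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0],
                        [0, 0, 1.0]])
        moved = st.copy()
        moved.pos1 = st.pos1 @ rot.T + [5.0, -3.0, 0.0]
        moved.pos2 = st.pos2 @ rot.T + [5.0, -3.0, 0.0]
        e1, _, _ = pairwise_energy_and_forces(moved, cfg, include_wall=False)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_nonfinite_coordinates_rejected(self):
        cfg = SimulationConfig(n_molecules=1, domain_radius=100.0)
        st = random_state(1, np.random.default_rng(0))
        st.pos1[0, 0] = np.nan
        with pytest.raises(ValueError):
            pairwise_energy_and_forces(st, cfg)
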