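import math

import numpy as np
import pytest

from nucleomc import _kernels
from nucleomc.constants import K_ANG_DEFAULT, K_BOND_DEFAULT, bjerrum_length
from nucleomc.energy import (
    INF,
    angle_deg,
    angle_energy,
    bond_energy,
    lj_pair,
    move_energy_delta,
    pair_electrostatic_hs,
    total_energy,
)
from nucleomc.model_core import (
    ChainTopology,
    ForceField,
    ParticleKind,
    SystemState,
    SystemConfig,
    build_system,
)
from conftest import random_rotation

LB = bjerrum_length()


class TestPairTerms:
    def test_unit_charges_at_bjerrum_length_cost_one_kt(self):
        assert pair_electrostatic_hs(1, 1, 1.0, 1.0, LB, LB) == pytest.approx(1.0)

    def test_hard_core_overlap_is_infinite(self):
        # two 2 Å monomers at 3.9 Å: inside contact
        assert pair_electrostatic_hs(-1, -1, 2.0, 2.0, 3.9, LB) == INF

    def test_zero_charge_is_zero_beyond_contact(self):
        assert pair_electrostatic_hs(0, 5, 2.0, 2.0, 4.5, LB) == 0.0

    def test_lj_zero_crossing_minimum_and_off(self):
        sigma = 5.8
        assert lj_pair(sigma, 1.5, sigma) == pytest.approx(0.0)
        rmin = 2 ** (1 / 6) * sigma
        assert lj_pair(rmin, 1.5, sigma) == pytest.approx(-1.5)
        assert lj_pair(3.0, 0.0, sigma) == 0.0

    def test_bond_energy_values_and_symmetry(self):
        assert bond_energy(5.0, K_BOND_DEFAULT, 5.0) == 0.0
        # 0.4 N/m converted to kT/Å²: (k/2)·1² ≈ 0.486 kT
        assert bond_energy(6.0, K_BOND_DEFAULT, 5.0) == pytest.approx(0.486, abs=0.001)
        assert bond_energy(4.0, K_BOND_DEFAULT, 5.0) == bond_energy(
            6.0, K_BOND_DEFAULT, 5.0
        )

    def test_angle_energy_values_and_quadratic_form(self):
        assert angle_energy(180.0, K_ANG_DEFAULT, 180.0) == 0.0
        u170 = angle_energy(170.0, K_ANG_DEFAULT, 180.0)
        assert u170 == pytest.approx(0.0413, abs=0.0002)
        assert angle_energy(160.0, K_ANG_DEFAULT, 180.0) == pytest.approx(4 * u170)

    def test_angle_degenerate_bond_vector(self):
        p = np.zeros(3)
        with pytest.raises(ValueError, match="degenerate"):
            angle_deg(p, p, np.array([1.0, 0.0, 0.0]))


def _bare_state(positions, valences, radii, chains=(), r_cell=1000.0,
                kinds=None):
    n = len(positions)
    return SystemState(
        positions=np.asarray(positions, dtype=float),
        kinds=np.asarray(
            kinds if kinds is not None
            else [ParticleKind.COUNTERION_POS] * n, dtype=np.int8
        ),
        valences=np.asarray(valences, dtype=np.int64),
        radii=np.asarray(radii, dtype=float),
        chains=list(chains),
        r_cell=r_cell,
    )


class TestTotalEnergy:
    def test_single_particle_all_terms_zero(self):
        st = _bare_state([[0.0, 0.0, 0.0]], [1], [2.0])
        e = total_energy(st, ForceField())
        assert e.u_total == 0.0

    def test_isolated_dimer_at_r0(self):
        st = _bare_state(
            [[0, 0, 0], [5.0, 0, 0]], [1, 1], [2.0, 2.0],
            chains=[ChainTopology(0, (0, 1))],
            kinds=[ParticleKind.HNS_MONOMER] * 2,
        )
        e = total_energy(st, ForceField(eps_pp=0.0))
        assert e.u_bond == 0.0
        assert e.u_elec_hs == pytest.approx(LB / 5.0, rel=1e-12)
        assert e.u_lj == 0.0

    def test_rotation_invariance(self, small_mixed_state):
        _, state, ff = small_mixed_state
        e0 = total_energy(state, ff)
        rot = state.copy()
        rot.positions = state.positions @ random_rotation(
            np.random.default_rng(5)
        ).T
        e1 = total_energy(rot, ff)
        for attr in ("u_elec_hs", "u_lj", "u_bond", "u_angle", "u_ext"):
            assert getattr(e1, attr) == pytest.approx(
                getattr(e0, attr), abs=1e-9
            )

    def test_escape_and_overlap_sentinels(self):
        out = _bare_state([[50.0, 0, 0]], [1], [2.0], r_cell=40.0)
        assert total_energy(out, ForceField()).u_ext == INF
        olap = _bare_state([[0, 0, 0], [3.0, 0, 0]], [1, 1], [2.0, 2.0])
        assert total_energy(olap, ForceField()).u_elec_hs == INF

    def test_neutral_zero_eps_reduces_to_hard_sphere(self):
        st = _bare_state([[0, 0, 0], [10.0, 0, 0]], [0, 0], [2.0, 2.0])
        e = total_energy(st, ForceField(eps_pp=0.0))
        assert e.u_total == 0.0

    def test_lj_intra_flag(self):
        st = _bare_state(
            [[0, 0, 0], [5.8, 0, 0]], [1, 1], [2.0, 2.0],
            chains=[ChainTopology(0, (0, 1))],
            kinds=[ParticleKind.HNS_MONOMER] * 2,
        )
        on = total_energy(st, ForceField(eps_pp=2.0, lj_intra=True))
        off = total_energy(st, ForceField(eps_pp=2.0, lj_intra=False))
        assert on.u_lj == pytest.approx(0.0)  # at sigma: LJ zero crossing
        assert off.u_lj == 0.0
        shifted = st.copy()
        shifted.positions[1, 0] = 2 ** (1 / 6) * 5.8
        assert total_energy(shifted, ForceField(eps_pp=2.0, lj_intra=True)
                            ).u_lj == pytest.approx(-2.0)


class TestMoveDelta:
    def test_null_move_is_zero(self, small_mixed_state):
        _, state, ff = small_mixed_state
        du = move_energy_delta(state, ff, [0], state.positions[[0]])
        assert du == 0.0

    @pytest.mark.parametrize("particle", [0, 3, 7, 12, 17])
    def test_matches_brute_force_difference(self, small_mixed_state, particle):
        _, state, ff = small_mixed_state
        rng = np.random.default_rng(100 + particle)
        for _ in range(5):
            new = state.positions[particle] + rng.uniform(-2, 2, 3)
            du = move_energy_delta(state, ff, [particle], new[None, :])
            trial = state.copy()
            trial.positions[particle] = new
            brute = total_energy(trial, ff).u_total - total_energy(
                state, ff
            ).u_total
            if du == INF:
                assert not math.isfinite(brute) or brute > 1e6
            else:
                assert du == pytest.approx(brute, abs=1e-9)

    def test_overlap_move_is_infinite(self, small_mixed_state):
        _, state, ff = small_mixed_state
        # drop a counterion onto the first DNA monomer
        ion = int(state.kind_indices(ParticleKind.COUNTERION_POS)[0])
        du = move_energy_delta(state, ff, [ion], state.positions[[0]])
        assert du == INF

    def test_multi_particle_move(self, small_mixed_state):
        _, state, ff = small_mixed_state
        members = np.array(state.chains[1].members)
        disp = np.array([0.5, -0.3, 0.2])
        du = move_energy_delta(state, ff, members,
                               state.positions[members] + disp)
        trial = state.copy()
        trial.positions[members] += disp
        brute = total_energy(trial, ff).u_total - total_energy(state, ff).u_total
        assert du == pytest.approx(brute, abs=1e-9)


class TestKernelAgreement:
    """The compiled kernels must reproduce the numpy reference exactly."""

    def test_total_energy_kernel_matches_reference(self, small_mixed_state):
        _, state, ff = small_mixed_state
        ka = state.kernel_arrays()
        terms = _kernels.total_energy_arrays(
            state.positions, ka["charge"], ka["radius"], ka["chain_id"],
            ka["chain_start"], ka["chain_len"], ka["chain_has_angles"],
            ka["is_hns"], state.r_cell, ff.bjerrum, ff.eps_pp, ff.sigma_pp,
            ff.lj_intra, ff.k_bond, ff.r0, ff.k_ang, ff.alpha0,
        )
        ref = total_energy(state, ff)
        np.testing.assert_allclose(
            terms,
            [ref.u_elec_hs, ref.u_lj, ref.u_bond, ref.u_angle, ref.u_ext],
            atol=1e-9,
        )

    def test_single_move_delta_kernel_matches_reference(self, small_mixed_state):
        _, state, ff = small_mixed_state
        ka = state.kernel_arrays()
        rng = np.random.default_rng(42)
        for _ in range(20):
            i = int(rng.integers(state.n_particles))
            new = state.positions[i] + rng.uniform(-3, 3, 3)
            du_k = _kernels._delta_single(
                state.positions, ka["charge"], ka["radius"], ka["chain_id"],
                ka["chain_start"], ka["chain_len"], ka["chain_has_angles"],
                ka["is_hns"], state.r_cell, ff.bjerrum, ff.eps_pp,
                ff.sigma_pp, ff.lj_intra, ff.k_bond, ff.r0, ff.k_ang,
                ff.alpha0, i, new[0], new[1], new[2],
            )
            du_ref = move_energy_delta(state, ff, [i], new[None, :])
            if du_ref == INF:
                assert du_k == INF
            else:
                assert du_k == pytest.approx(du_ref, abs=1e-9)

    def test_chain_translate_delta_kernel_matches_reference(
        self, small_mixed_state
    ):
        _, state, ff = small_mixed_state
        ka = state.kernel_arrays()
        rng = np.random.default_rng(43)
        for c in range(len(state.chains)):
            disp = rng.uniform(-2, 2, 3)
            du_k = _kernels._delta_chain_translate(
                state.positions, ka["charge"], ka["radius"], ka["chain_id"],
                ka["chain_start"], ka["chain_len"], ka["is_hns"],
                state.r_cell, ff.bjerrum, ff.eps_pp, ff.sigma_pp, c,
                disp[0], disp[1], disp[2],
            )
            members = np.array(state.chains[c].members)
            du_ref = move_energy_delta(
                state, ff, members, state.positions[members] + disp
            )
            if du_ref == INF:
                assert du_k == INF
            else:
                assert du_k == pytest.approx(du_ref, abs=1e-9)
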