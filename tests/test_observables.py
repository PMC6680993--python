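import math

import numpy as np
import pytest

from nucleomc.model_core import (
    ChainTopology,
    ForceField,
    McSchedule,
    ParticleKind,
    SystemConfig,
    build_system,
)
from nucleomc.observables import (
    bjerrum_length,
    effective_crowder_charge,
    end_to_end,
    histogram_series,
    prg_histogram,
    radius_of_gyration,
    radius_of_gyration_rms,
    rdf,
    ree_rg_rms_ratio,
    rg_series,
    sphere_pair_distance_cdf,
    subbatch_errors,
)
from nucleomc.sampler import MoveSet, Trajectory, run_mc
from conftest import make_schedule


def rod(n=120, spacing=5.0):
    return np.column_stack(
        [np.arange(n) * spacing, np.zeros(n), np.zeros(n)]
    )


class TestChainMeasures:
    def test_coincident_monomers_have_zero_rg(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_two_monomers_at_d_give_d_over_2(self):
        coords = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(4.0)

    def test_straight_rod_mean_distance_form(self):
        # discrete oracle: mean_i |i - 59.5| * 5 over i=0..119
        expected = np.abs(np.arange(120) - 59.5).mean() * 5.0
        assert expected == pytest.approx(150.0)
        assert radius_of_gyration(rod()) == pytest.approx(expected)

    def test_rod_rms_form_exceeds_mean_form(self):
        r = rod()
        rms = radius_of_gyration_rms(r)
        expected = math.sqrt(np.mean((np.abs(np.arange(120) - 59.5) * 5) ** 2))
        assert rms == pytest.approx(expected)
        assert rms > radius_of_gyration(r)

    def test_end_to_end_rod_and_loop(self):
        assert end_to_end(rod()) == pytest.approx(595.0)
        loop = np.vstack([rod(10), rod(1)])
        assert end_to_end(loop) == 0.0

    def test_rod_shape_ratio_approaches_sqrt_12(self):
        # discrete N-bead rod: Ree/Rg = sqrt(12(N-1)/(N+1)) -> sqrt(12)
        n = 120
        traj = _traj_from_frames(rod(n)[None, :, :])
        expected = math.sqrt(12.0 * (n - 1) / (n + 1))
        assert ree_rg_rms_ratio(traj) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(math.sqrt(12.0), rel=0.01)


def _traj_from_frames(frames, kinds=None, valences=None, radii=None,
                      chains=None, r_cell=1000.0, n_subbatches=2):
    f, n, _ = frames.shape
    if chains is None:
        chains = [ChainTopology(0, tuple(range(n)), has_angles=n >= 3)]
    return Trajectory(
        positions=np.asarray(frames, dtype=float),
        sweeps=np.arange(f),
        energies=np.zeros((f, 5)),
        kinds=np.asarray(
            kinds if kinds is not None else [0] * n, dtype=np.int8
        ),
        valences=np.asarray(
            valences if valences is not None else [-1] * n, dtype=np.int64
        ),
        radii=np.asarray(radii if radii is not None else [2.0] * n),
        chains=chains,
        r_cell=r_cell,
        n_subbatches=n_subbatches,
    )


class TestSubbatchErrors:
    def test_constant_series_has_zero_error(self):
        mean, err = subbatch_errors(np.full(100, 3.5), 10)
        assert mean == 3.5
        assert err == 0.0

    def test_alternating_series_has_zero_mean(self):
        series = np.tile([1.0, -1.0], 50)
        mean, _ = subbatch_errors(series, 10)
        assert mean == pytest.approx(0.0)

    def test_iid_normal_error_matches_closed_form(self):
        rng = np.random.default_rng(99)
        sigma, n = 2.0, 4000
        _, err = subbatch_errors(rng.normal(0, sigma, n), 20)
        expected = sigma / math.sqrt(n)
        # std of the error estimate itself is ~ expected/sqrt(2(B-1))
        assert abs(err - expected) < 4 * expected / math.sqrt(2 * 19)

    def test_indivisible_series_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            subbatch_errors(np.arange(10.0), 3)


class TestBjerrum:
    def test_water_at_room_temperature_rounds_to_7(self):
        lb = bjerrum_length(78.4, 298.15)
        assert lb == pytest.approx(7.15, abs=0.01)
        assert round(lb) == 7

    def test_scaling_with_permittivity(self):
        assert bjerrum_length(2 * 78.4, 298.15) == pytest.approx(
            bjerrum_length(78.4, 298.15) / 2
        )
        assert bjerrum_length(1e12, 298.15) < 1e-9


class TestHistograms:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        h = histogram_series(rng.normal(50, 5, 1000), 10, 2.0)
        assert h.density.sum() * h.bin_width == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.errors >= 0)

    def test_prg_mean_matches_series_mean(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(0, 10, size=(200, 12, 3))
        traj = _traj_from_frames(frames, n_subbatches=10)
        h = prg_histogram(traj, 0, bin_width=0.5)
        series = rg_series(traj, 0)
        assert h.mean() == pytest.approx(series.mean(), abs=0.3)

    def test_rg_bounded_by_max_com_distance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 10, size=(30, 3))
        com = coords.mean(axis=0)
        assert radius_of_gyration(coords) <= np.max(
            np.linalg.norm(coords - com, axis=1)
        )


class TestRdf:
    def test_sphere_pair_distance_cdf_limits(self):
        assert sphere_pair_distance_cdf(np.array([0.0]), 50.0)[0] == 0.0
        assert sphere_pair_distance_cdf(np.array([100.0]), 50.0)[0] == pytest.approx(1.0)

    def test_ideal_gas_gives_unity(self):
        # uniform non-interacting points in the sphere: g(r) == 1 up to noise
        rng = np.random.default_rng(5)
        r_cell, n, f = 50.0, 150, 200
        pts = rng.normal(size=(f, n, 3))
        pts /= np.linalg.norm(pts, axis=2, keepdims=True)
        pts *= r_cell * rng.random(size=(f, n, 1)) ** (1 / 3)
        traj = _traj_from_frames(
            pts, kinds=[int(ParticleKind.CROWDER)] * n,
            valences=[0] * n, radii=[0.0] * n,
            chains=[], r_cell=r_cell, n_subbatches=10,
        )
        curve = rdf(traj, ParticleKind.CROWDER, ParticleKind.CROWDER,
                    bin_width=2.0)
        good = curve.ref_counts > 2000
        assert np.all(np.abs(curve.g[good] - 1.0) < 0.1)
        assert abs(curve.g[good].mean() - 1.0) < 0.01

    def test_two_fixed_particles_single_bin(self):
        d = 12.3
        frames = np.tile(
            np.array([[0.0, 0, 0], [d, 0, 0]]), (5, 1, 1)
        )
        traj = _traj_from_frames(
            frames, kinds=[int(ParticleKind.CROWDER)] * 2, valences=[0, 0],
            chains=[], r_cell=50.0, n_subbatches=1,
        )
        curve = rdf(traj, ParticleKind.CROWDER, ParticleKind.CROWDER,
                    bin_width=1.0)
        occupied = curve.r[curve.g > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(12.5)

    def test_hard_spheres_vanish_inside_contact(self):
        cfg = SystemConfig(n_dna=0, n_hns=1, n_crow=25, z_crow=0,
                           r_cell=60.0, seed=9,
                           mc=make_schedule(equil_sweeps=50, prod_sweeps=500,
                                            seed=9))
        state = build_system(cfg)
        res = run_mc(state, ForceField.from_config(cfg), cfg.mc, MoveSet())
        curve = rdf(res.trajectory, ParticleKind.CROWDER,
                    ParticleKind.CROWDER, bin_width=1.0)
        inside = curve.r < 20.0  # twice the crowder radius
        assert np.all(curve.g[inside] == 0.0)
        assert curve.g[~inside].max() > 0.5

    def test_missing_kind_is_an_error(self):
        traj = _traj_from_frames(np.zeros((2, 4, 3)))
        with pytest.raises(ValueError, match="no particles"):
            rdf(traj, ParticleKind.DNA_MONOMER, ParticleKind.CROWDER)


class TestEffectiveCharge:
    def _traj(self, crow_pos, ion_pos, z_crow=-5, n_subbatches=2):
        nc, ni = len(crow_pos), len(ion_pos)
        frames = np.concatenate([crow_pos, ion_pos])[None, :, :]
        frames = np.tile(frames, (2, 1, 1))
        return _traj_from_frames(
            frames,
            kinds=[int(ParticleKind.CROWDER)] * nc
            + [int(ParticleKind.COUNTERION_POS)] * ni,
            valences=[z_crow] * nc + [1] * ni,
            radii=[10.0] * nc + [2.0] * ni,
            chains=[], r_cell=100.0, n_subbatches=n_subbatches,
        )

    def test_no_ions_in_shell_gives_bare_charge(self):
        traj = self._traj(
            np.array([[0.0, 0, 0]]), np.array([[50.0, 0, 0], [0, 60.0, 0]])
        )
        z, err = effective_crowder_charge(traj, shell=7.0)
        assert z == -5.0
        assert err == 0.0

    def test_condensed_ions_reduce_charge_magnitude(self):
        traj = self._traj(
            np.array([[0.0, 0, 0]]),
            np.array([[12.0, 0, 0], [0, 14.0, 0], [0, 0, 40.0]]),
        )
        z, _ = effective_crowder_charge(traj, shell=7.0)
        assert z == -3.0  # two ions inside the 17 Å shell

    def test_equidistant_ion_counted_once(self):
        traj = self._traj(
            np.array([[-10.0, 0, 0], [10.0, 0, 0]]),
            np.array([[0.0, 0, 0]]),  # equidistant from both crowders
        )
        z, _ = effective_crowder_charge(traj, shell=7.0)
        # one ion, two crowders: mean count per crowder is 0.5, not 1
        assert z == -4.5

    def test_requires_crowders_and_ions(self):
        traj = _traj_from_frames(np.zeros((2, 3, 3)))
        with pytest.raises(ValueError):
            effective_crowder_charge(traj)
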