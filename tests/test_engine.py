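"""MD engine: potentials, conservation laws, thermostat/barostat behavior."""

import math

import numpy as np
import pytest

import cgbilayer as cg
from cgbilayer import constants as c
from cgbilayer.engine import (
    EngineConfig,
    EngineError,
    _Evaluator,
    energy_forces,
    integrate,
    minimize,
)
from cgbilayer.ewald import ewald_params, ewald_sum
from cgbilayer.system import System

from conftest import make_lj_gas, make_two_beads, nve_config


class TestLennardJones:
    def test_force_zero_at_minimum(self, ff):
        eps, sig = ff.lookup("C1", "C1")
        s = make_two_beads(2 ** (1 / 6) * sig)
        _, f = energy_forces(s, ff, nve_config())
        assert np.abs(f).max() < 1e-10

    def test_newtons_third_law(self, ff):
        s = make_lj_gas(n=40, box=30.0, seed=2)
        _, f = energy_forces(s, ff, nve_config())
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_potential_shifted_to_zero_at_cutoff(self, ff):
        cfg = nve_config()
        e_in, _ = energy_forces(s := make_two_beads(cfg.r_vdw - 1e-7), ff, cfg)
        e_out, _ = energy_forces(make_two_beads(cfg.r_vdw + 1e-7), ff, cfg)
        assert e_out == 0.0
        assert abs(e_in) < 1e-6  # continuous through the cutoff

    def test_bad_contact_diagnostic(self, ff):
        with pytest.warns(UserWarning, match="bad contact"):
            energy_forces(make_two_beads(0.5), ff, nve_config())

    def test_cutoff_exceeding_half_box_rejected(self, ff):
        s = make_two_beads(5.0, box=20.0)
        with pytest.raises(EngineError, match="cutoff"):
            energy_forces(s, ff, nve_config())


class TestEwald:
    """Tinfoil Ewald vs a brute-force periodic image sum.

    The direct sum over expanding image shells converges to the
    vacuum-boundary energy, which exceeds the tinfoil result by the
    surface-dipole term 2*pi*|M|^2 / (3V).
    """

    def _direct_sum(self, coords, q, box, pref, nmax):
        e = 0.0
        shifts = range(-nmax, nmax + 1)
        for nx in shifts:
            for ny in shifts:
                for nz in shifts:
                    shift = np.array([nx, ny, nz]) * box
                    for i in range(len(q)):
                        for j in range(len(q)):
                            d = coords[i] - coords[j] + shift
                            r = np.linalg.norm(d)
                            if r == 0:
                                continue
                            e += 0.5 * pref * q[i] * q[j] / r
        return e

    def test_two_charge_pair_vs_image_sum(self, ff):
        box = np.array([20.0, 20.0, 20.0])
        coords = np.array([[5.0, 5.0, 5.0], [9.0, 5.0, 5.0]])
        q = np.array([1.0, -1.0])
        pref = ff.coulomb_constant / ff.relative_dielectric
        params = ewald_params(box, 9.0, 1e-6)
        e_ewald, _, _ = ewald_sum(coords, q, box, pref, 9.0, params)
        m = (q[:, None] * coords).sum(axis=0)
        surface = 2 * math.pi * pref * (m @ m) / (3 * box.prod())
        e_direct = self._direct_sum(coords, q, box, pref, nmax=12)
        assert abs((e_direct - surface - e_ewald) / e_ewald) < 1e-4

    def test_forces_match_finite_difference(self, ff):
        box = np.array([18.0, 22.0, 20.0])
        coords = np.array([[4.0, 5.0, 5.0], [9.0, 7.0, 6.0], [6.0, 12.0, 9.0]])
        q = np.array([1.0, -1.0, 0.0])
        pref = ff.coulomb_constant / ff.relative_dielectric
        params = ewald_params(box, 8.0, 1e-8)
        _, f, _ = ewald_sum(coords, q, box, pref, 8.0, params)
        h = 1e-5
        for axis in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[0, axis] += h
            cm[0, axis] -= h
            ep, _, _ = ewald_sum(cp, q, box, pref, 8.0, params)
            em, _, _ = ewald_sum(cm, q, box, pref, 8.0, params)
            assert f[0, axis] == pytest.approx(-(ep - em) / (2 * h), rel=1e-4,
                                               abs=1e-6)

    def test_non_neutral_rejected(self):
        box = np.array([20.0] * 3)
        with pytest.raises(ValueError, match="neutral"):
            ewald_sum(np.zeros((1, 3)), np.array([1.0]), box, 1.0, 9.0,
                      ewald_params(box, 9.0))


class TestIntegration:
    def test_free_particle_linear_motion(self, ff):
        s = make_two_beads(30.0)
        s.velocities = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        cfg = nve_config(dt_fs=20.0)
        _, fin, _ = integrate(s, ff, cfg, n_steps=10, traj_stride=10,
                              initialize_velocities=False)
        assert fin.coords[0, 0] == pytest.approx(10.0 + 10 * 0.02 * 1.0)
        assert fin.coords[1, 1] == pytest.approx(10.0 + 10 * 0.02 * 2.0)

    def test_same_seed_identical_trajectory(self, ff):
        cfg = EngineConfig(coulomb="none", barostat="none", seed=42)
        s = make_lj_gas(n=32, box=30.0)
        t1, _, _ = integrate(s, ff, cfg, n_steps=50, traj_stride=10)
        t2, _, _ = integrate(s, ff, cfg, n_steps=50, traj_stride=10)
        assert np.array_equal(t1.coords, t2.coords)

    def _nve_drift(self, ff, dt_fs, steps, seed=5):
        cfg = nve_config(dt_fs=dt_fs)
        s = make_lj_gas(n=64, box=40.0, seed=seed)
        _, _, log = integrate(s, ff, cfg, n_steps=steps, traj_stride=steps,
                              log_stride=5, initialize_velocities=False)
        etot = np.array([rec["potential"] + rec["kinetic"] for rec in log])
        return np.abs(etot - etot[0]).max() / s.n_beads

    def test_nve_drift_bounded_and_converges_with_step(self, ff):
        # step-halving oracle: velocity Verlet error is O(dt^2)
        d20 = self._nve_drift(ff, 20.0, 3000)
        d10 = self._nve_drift(ff, 10.0, 6000)
        assert d20 < 0.05  # kJ/mol per bead over the full run
        assert d10 < 0.6 * d20

    def test_momentum_conserved_in_nve(self, ff):
        s = make_lj_gas(n=64, box=40.0, seed=8)
        _, fin, _ = integrate(s, ff, nve_config(), n_steps=1500,
                              traj_stride=1500, initialize_velocities=False)
        p = (fin.masses[:, None] * fin.velocities).sum(axis=0)
        assert np.abs(p).max() < 1e-8

    def test_thermostat_holds_310K(self, ff):
        s = make_lj_gas(n=500, box=60.0, seed=7)
        cfg = EngineConfig(thermostat="nose-hoover", barostat="none",
                           coulomb="none", seed=7)
        _, _, log = integrate(s, ff, cfg, n_steps=2500, traj_stride=2500,
                              log_stride=10)
        temps = np.array([rec["temperature"] for rec in log])
        production = temps[len(temps) // 2:]
        assert abs(production.mean() - 310.0) / 310.0 < 0.02

    def test_ideal_gas_pressure(self, ff):
        # beads farther apart than the cutoff never interact: P V = N k T
        n, box = 216, 180.0
        m = 6
        pts = [((i + 0.5) * 30.0, (j + 0.5) * 30.0, (k + 0.5) * 30.0)
               for i in range(m) for j in range(m) for k in range(m)]
        s = System(
            coords=np.array(pts), velocities=np.zeros((n, 3)),
            types=np.array(["P4"] * n, dtype=object), charges=np.zeros(n),
            masses=np.full(n, 72.0), mol_index=np.arange(n),
            species=["W"] * n, box=np.array([box] * 3),
        )
        cg.maxwell_velocities(s, 310.0, seed=3)
        _, _, log = integrate(s, ff, nve_config(), n_steps=60,
                              traj_stride=60, log_stride=10,
                              initialize_velocities=False)
        p_mean = np.mean([0.5 * (r["p_lateral"] * 2 + r["p_normal"]) / 1.5
                          for r in log])  # mean of the three diagonals
        p_ideal = n * c.KB * 310.0 / box**3 / c.BAR_TO_KJMOL_A3
        # velocities carry 3N-3 degrees of freedom
        assert p_mean == pytest.approx(p_ideal * (1 - 1 / n), rel=1e-6)

    def test_barostat_lateral_isotropy_and_bead_count(self, ff):
        s = make_lj_gas(n=64, box=40.0, seed=6)
        cfg = EngineConfig(coulomb="none", seed=6,
                           pressure_mode="semi-isotropic")
        traj, fin, _ = integrate(s, ff, cfg, n_steps=300, traj_stride=50)
        assert fin.n_beads == 64
        # x and y are coupled: they scale together every step
        ratios = traj.boxes[:, 0] / traj.boxes[:, 1]
        assert np.allclose(ratios, ratios[0])
        assert not np.allclose(traj.boxes[0], traj.boxes[-1])  # box moved


class TestMinimize:
    def test_already_minimal_pair_unchanged(self, ff):
        eps, sig = ff.lookup("C1", "C1")
        s = make_two_beads(2 ** (1 / 6) * sig)
        out = minimize(s, ff, nve_config())
        e0, _ = energy_forces(s, ff, nve_config())
        e1, _ = energy_forces(out, ff, nve_config())
        assert e1 <= e0 + 1e-12
        assert np.abs(out.coords - s.coords).max() < 0.1

    def test_overlapping_pair_descends(self, ff):
        s = make_two_beads(3.0)
        e0, _ = energy_forces(s, ff, nve_config())
        out = minimize(s, ff, nve_config())
        e1, _ = energy_forces(out, ff, nve_config())
        assert e1 < e0

    def test_three_bead_minimum_matches_grid_oracle(self, ff):
        """The LJ trimer ground state is an equilateral triangle; scan its
        side length on a fine grid as an independent oracle."""
        eps, sig = ff.lookup("C1", "C1")

        def trimer_energy(d):
            rc = 12.5
            def pair(r):
                if r >= rc:
                    return 0.0
                sr6 = (sig / r) ** 6
                sr6c = (sig / rc) ** 6
                return 4 * eps * ((sr6**2 - sr6) - (sr6c**2 - sr6c))
            return 3 * pair(d)

        grid = np.linspace(0.8 * sig, 2.0 * sig, 4001)
        e_oracle = min(trimer_energy(d) for d in grid)

        coords = np.array([[20.0, 20.0, 20.0], [25.5, 20.2, 20.0],
                           [22.5, 24.5, 19.8]])
        s = System(
            coords=coords, velocities=np.zeros((3, 3)),
            types=np.array(["C1"] * 3, dtype=object), charges=np.zeros(3),
            masses=np.full(3, 72.0), mol_index=np.arange(3),
            species=["X"] * 3, box=np.array([60.0] * 3),
        )
        out = minimize(s, ff, nve_config(), max_iter=500)
        e_min, f_min = energy_forces(out, ff, nve_config())
        assert e_min == pytest.approx(e_oracle, abs=1e-3)
        assert np.abs(f_min).max() < 0.05


class TestEngineConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(dt_fs=-1)
        with pytest.raises(ValueError):
            EngineConfig(thermostat="bogus")
        with pytest.raises(ValueError):
            EngineConfig(effective_time_factor=0)

    def test_effective_times_scaled_by_factor(self, ff):
        s = make_lj_gas(n=27, box=30.0, seed=1)
        cfg = nve_config(dt_fs=20.0)
        traj, _, _ = integrate(s, ff, cfg, n_steps=100, traj_stride=20,
                               initialize_velocities=False)
        assert traj.effective_time_factor == 4.0
        assert traj.effective_times[-1] == pytest.approx(4 * traj.times[-1])


class TestBilayerSmoke:
    def test_small_bilayer_minimize_then_npt(self, ff):
        """End-to-end sanity on a reduced bilayer: energies stay finite,
        the box stays positive, temperature is controlled."""
        comp = cg.Composition(leaflet_counts={"POPC": 16}, n_water_beads=500)
        s = cg.build_bilayer(comp, (33.0, 33.0, 80.0), seed=2)
        s = cg.solvate(s, 500, 0.3, seed=3)
        s = minimize(s, ff, max_iter=60)
        cfg = EngineConfig(seed=4)
        traj, fin, log = integrate(s, ff, cfg, n_steps=60, traj_stride=20,
                                   log_stride=20)
        assert all(np.isfinite(rec["potential"]) for rec in log)
        assert np.all(fin.box > 0)
        assert traj.n_frames == 4
        assert 100 < log[-1]["temperature"] < 600
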