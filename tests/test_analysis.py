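"""Bilayer metrics: APL, thickness, P2, MSD and diffusion fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cgbilayer as cg
from cgbilayer.analysis import (
    area_per_lipid,
    fit_diffusion,
    hydrophobic_thickness,
    lipid_lateral_msd,
    msd_lateral,
    p2,
    p2_bond,
    p2_tail,
)
from cgbilayer.synthdata import SyntheticSpec, gen_bilayer_trajectory, p2_of_tilt
from cgbilayer.trajectory import Trajectory

MAGIC_ANGLE = math.degrees(math.acos(1 / math.sqrt(3)))


def small_bilayer(**kw):
    spec = SyntheticSpec(**{
        "lipids_per_leaflet": 10, "n_frames": 40, "seed": 7, **kw})
    return gen_bilayer_trajectory(spec)


class TestAreaPerLipid:
    def test_worked_example_62p4_box_58_lipids(self):
        traj = Trajectory(
            coords=np.zeros((1, 1, 3)) + 1.0,
            boxes=np.array([[62.4, 62.4, 90.0]]),
            times=np.array([0.0]),
        )
        stat = area_per_lipid(traj, 58)
        assert stat.mean == pytest.approx(62.4 * 62.4 / 58)
        assert round(stat.mean) == 67  # the headline packing density

    def test_unit_box_single_lipid(self):
        traj = Trajectory(coords=np.ones((1, 1, 3)),
                          boxes=np.array([[1.0, 1.0, 1.0]]),
                          times=np.array([0.0]))
        assert area_per_lipid(traj, 1).mean == 1.0

    def test_constant_box_zero_sd(self):
        traj, _, _ = small_bilayer()
        stat = area_per_lipid(traj, 10)
        assert stat.sd == 0.0

    def test_zero_lipids_rejected(self):
        traj, _, _ = small_bilayer()
        with pytest.raises(ValueError):
            area_per_lipid(traj, 0)


class TestHydrophobicThickness:
    def test_constructed_c1_planes(self):
        traj, system, _ = small_bilayer(thickness=14.8)
        stat = hydrophobic_thickness(traj, system)
        assert stat.mean == pytest.approx(14.8, abs=1e-9)

    def test_translation_invariance(self):
        traj, system, _ = small_bilayer(thickness=12.0)
        shifted = Trajectory(
            coords=traj.coords + np.array([0.0, 0.0, 3.0]),
            boxes=traj.boxes, times=traj.times,
            effective_time_factor=traj.effective_time_factor,
        )
        a = hydrophobic_thickness(traj, system).mean
        b = hydrophobic_thickness(shifted, system).mean
        assert a == pytest.approx(b, abs=1e-9)

    def test_matches_density_profile_oracle(self):
        """Independent estimate: distance between the half-max edges of the
        tail-bead z histogram."""
        traj, system, _ = small_bilayer(thickness=14.8, n_frames=20)
        tails = system.lipid_bead_indices("c1")
        z = traj.coords[:, tails, 2].ravel()
        hist, edges = np.histogram(z, bins=np.arange(z.min() - 1,
                                                     z.max() + 1, 0.5))
        half = hist.max() / 2
        occupied = np.nonzero(hist >= half)[0]
        centers = 0.5 * (edges[:-1] + edges[1:])
        oracle = centers[occupied[-1]] - centers[occupied[0]]
        stat = hydrophobic_thickness(traj, system)
        assert stat.mean == pytest.approx(oracle, abs=1.0)


class TestP2:
    def test_parallel_vectors_give_one(self):
        v = np.tile([0.0, 0.0, 2.5], (100, 1))
        assert p2(v) == pytest.approx(1.0)

    def test_perpendicular_vectors_give_minus_half(self):
        v = np.tile([1.3, -0.4, 0.0], (100, 1))
        assert p2(v) == pytest.approx(-0.5)

    def test_magic_angle_gives_zero(self):
        t = math.radians(MAGIC_ANGLE)
        v = np.array([[math.sin(t), 0.0, math.cos(t)]])
        assert p2(v) == pytest.approx(0.0, abs=1e-4)

    def test_isotropic_vectors_give_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10**6, 3))
        val = p2(v)
        se = math.sqrt(0.2 / 10**6)  # var of (3cos^2-1)/2 is 1/5
        assert abs(val) < 3 * se

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            p2(np.zeros((1, 3)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(50, 3))
        norms = np.linalg.norm(v, axis=1)
        v = v[norms > 1e-12]
        assert -0.5 - 1e-12 <= p2(v) <= 1.0 + 1e-12

    def test_rotation_about_normal_invariant(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(200, 3))
        phi = 0.7
        rot = np.array([[math.cos(phi), -math.sin(phi), 0],
                        [math.sin(phi), math.cos(phi), 0],
                        [0, 0, 1]])
        assert p2(v) == pytest.approx(p2(v @ rot.T), abs=1e-12)


class TestP2BondAndTail:
    def test_vertical_tails_all_one(self):
        traj, system, _ = small_bilayer(bond_tilts_deg=(0.0, 0.0, 0.0))
        df = p2_bond(traj, system)
        assert np.allclose(df["p2"], 1.0)
        dft = p2_tail(traj, system)
        assert np.allclose(dft["p2"], 1.0)

    def test_order_decreases_down_the_chain(self):
        traj, system, _ = small_bilayer(bond_tilts_deg=(20.0, 35.0, 50.0))
        df = p2_bond(traj, system).set_index("bond")
        by_bond = df.groupby(level=0)["p2"].mean()
        assert by_bond["c1-c2"] > by_bond["c2-c3"] > by_bond["c3-c4"]
        for label, tilt in zip(("c1-c2", "c2-c3", "c3-c4"), (20.0, 35.0, 50.0)):
            assert by_bond[label] == pytest.approx(p2_of_tilt(tilt), abs=1e-6)

    def test_matches_bruteforce_oracle(self):
        traj, system, _ = small_bilayer(n_frames=6, lipids_per_leaflet=3)
        df = p2_bond(traj, system).set_index(["species", "chain", "bond"])
        # naive loops over frames, lipids, tails, bonds
        acc: dict = {}
        for m in system.lipid_mols():
            topo = system.topologies[system.species[m]]
            base = system.mol_slice(int(m)).start
            for tail in topo.tails:
                for k, label in enumerate(("c1-c2", "c2-c3", "c3-c4")):
                    i, j = base + tail.beads[k], base + tail.beads[k + 1]
                    for f in range(traj.n_frames):
                        d = traj.coords[f, j] - traj.coords[f, i]
                        d -= np.round(d / traj.boxes[f]) * traj.boxes[f]
                        c2 = d[2] ** 2 / (d @ d)
                        acc.setdefault(
                            (system.species[m], tail.kind, label), []
                        ).append(1.5 * c2 - 0.5)
        for key, vals in acc.items():
            assert df.loc[key, "p2"] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_tail_fixed_tilt_closed_form(self):
        traj, system, _ = small_bilayer(bond_tilts_deg=(25.0, 25.0, 25.0))
        dft = p2_tail(traj, system)
        assert np.allclose(dft["p2"], p2_of_tilt(25.0), atol=1e-9)

    def test_species_average_is_mean_of_chains(self):
        traj, system, _ = small_bilayer(species="POPC")
        dft = p2_tail(traj, system)
        overall = dft["p2"].mean()
        per_chain = dft.set_index("chain")["p2"]
        assert overall == pytest.approx(
            (per_chain["pal"] + per_chain["ol"]) / 2)


class TestMSD:
    def test_static_configuration_zero(self):
        pos = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (20, 1, 1))
        _, msd = msd_lateral(pos)
        assert np.allclose(msd, 0.0)

    def test_uniform_drift_removed(self):
        t = np.arange(30)[:, None, None]
        pos = np.tile([[0.0, 0.0], [5.0, 5.0]], (30, 1, 1)) + 0.7 * t
        _, msd = msd_lateral(pos, remove_drift=True)
        assert np.allclose(msd, 0.0, atol=1e-20)

    def test_random_walk_slope(self):
        traj = cg.gen_brownian(100, 2.0e-7, 1.0, 1200, seed=5)
        lags, msd = msd_lateral(traj.unwrapped()[:, :, :2])
        fit = fit_diffusion(lags * 1.0, msd)
        assert fit.d_cm2_s == pytest.approx(2.0e-7, rel=0.05)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError):
            msd_lateral(np.zeros((1, 3, 2)))


class TestFitDiffusion:
    def test_exact_line_recovered(self):
        t = np.arange(101) * 1.0
        d0 = 2.2  # A^2/ns
        fit = fit_diffusion(t, 4 * d0 * t)
        assert fit.d_cm2_s == pytest.approx(d0 * 1e-7, rel=1e-12)

    def test_doubling_effective_factor_halves_d(self):
        t = np.arange(101) * 1.0
        msd = 4 * 2.2 * t
        d1 = fit_diffusion(t, msd, effective_time_factor=1.0).d_cm2_s
        d2 = fit_diffusion(t, msd, effective_time_factor=2.0).d_cm2_s
        assert d2 == pytest.approx(d1 / 2)

    def test_negative_slope_clamped_with_warning(self):
        t = np.arange(101) * 1.0
        with pytest.warns(UserWarning, match="negative"):
            fit = fit_diffusion(t, -3.0 * t)
        assert fit.d_cm2_s == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="lag points"):
            fit_diffusion(np.arange(5.0), np.arange(5.0))

    def test_unbiased_over_seeds(self):
        """At the study scale (58 walkers, 2000 frames) the fitted D is
        unbiased within 2 standard errors of the seed ensemble."""
        truth = 2.2e-7
        fits = []
        for seed in range(12):
            traj = cg.gen_brownian(58, truth, 1.0, 2000, seed=seed)
            lags, msd = msd_lateral(traj.unwrapped()[:, :, :2])
            fits.append(fit_diffusion(lags * 1.0, msd).d_cm2_s)
        fits = np.array(fits)
        sem = fits.std(ddof=1) / math.sqrt(len(fits))
        assert abs(fits.mean() - truth) < 2 * sem


class TestInvariances:
    def test_lateral_translation_leaves_metrics_unchanged(self):
        traj, system, _ = small_bilayer()
        shifted = Trajectory(
            coords=traj.coords + np.array([7.0, -3.0, 0.0]),
            boxes=traj.boxes, times=traj.times,
            effective_time_factor=traj.effective_time_factor,
        )
        assert hydrophobic_thickness(shifted, system).mean == pytest.approx(
            hydrophobic_thickness(traj, system).mean, abs=1e-9)
        a = p2_bond(traj, system)["p2"].to_numpy()
        b = p2_bond(shifted, system)["p2"].to_numpy()
        assert np.allclose(a, b, atol=1e-12)
        la, ma = lipid_lateral_msd(traj, system)
        lb, mb = lipid_lateral_msd(shifted, system)
        assert np.allclose(ma, mb, atol=1e-9)

    def test_leaflet_assignment_stable(self):
        traj, system, _ = small_bilayer(n_frames=30)
        from cgbilayer.analysis import _leaflet_sign

        signs = _leaflet_sign(traj, system)
        assert np.all(signs == signs[0])
        assert signs[0].sum() == 0  # equal split
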