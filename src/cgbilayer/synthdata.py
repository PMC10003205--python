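"""Synthetic bilayer trajectories with exactly known ground truth.

The generator builds two leaflets of pseudo-lipids that reuse the real
lipid topologies (bead labels, chain kinds), so the analysis code cannot
distinguish a synthetic trajectory from an engine-produced one, while
every target metric is imposed by construction:

* the lateral box area is APL x lipids-per-leaflet, exactly;
* the first tail beads (C1) sit on planes at +/- thickness/2, exactly;
* each tail bond has a fixed polar tilt from the normal, with the bonds of
  one tail sharing a uniformly random azimuth per frame — so the per-bond
  P2 is the closed form (3 cos^2 theta_b - 1)/2 and the end-to-end (C1->C4)
  P2 follows from the vector sum of the bonds in closed form;
* lipid centers follow independent 2-D Brownian motion with a prescribed
  diffusion coefficient.

Azimuths are uniform, so tilted tails have no preferred lateral direction
and P2 depends only on the polar angle. Times are generated directly on
the effective clock (factor 1). What the generator deliberately does NOT
emulate: inter-lipid correlations, undulations, protrusions, or solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .forcefield import ForceFieldTables, default_forcefield, lipid_topology
from .system import System
from .trajectory import Trajectory

__all__ = ["SyntheticSpec", "gen_bilayer_trajectory", "gen_brownian",
           "p2_of_tilt", "tilt_of_p2"]

BOND_LENGTH = 4.7  # A, tail bond length used for synthetic tails


def p2_of_tilt(theta_deg: float) -> float:
    """Closed-form P2 of a vector at fixed polar angle theta."""
    return 0.5 * (3 * math.cos(math.radians(theta_deg)) ** 2 - 1)


def tilt_of_p2(p2_value: float) -> float:
    """Polar angle (deg) whose fixed-tilt P2 equals ``p2_value``."""
    if not -0.5 <= p2_value <= 1.0:
        raise ValueError("P2 must be in [-0.5, 1]")
    return math.degrees(math.acos(math.sqrt((2 * p2_value + 1) / 3)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth targets for one synthetic bilayer trajectory."""

    species: str = "POPC"
    protonated: bool = False
    lipids_per_leaflet: int = 58
    n_frames: int = 200
    frame_interval_ns: float = 1.0  # effective ns
    apl: float = 67.1  # A^2
    thickness: float = 14.8  # A, distance between C1 planes
    bond_tilts_deg: tuple[float, float, float] = (20.0, 35.0, 50.0)
    d_cm2_s: float = 2.2e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet <= 0 or self.n_frames < 2:
            raise ValueError("need >= 1 lipid per leaflet and >= 2 frames")
        if min(self.apl, self.thickness, self.frame_interval_ns) <= 0:
            raise ValueError("APL, thickness and frame interval must be > 0")
        if self.d_cm2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        for t in self.bond_tilts_deg:
            if not 0 <= t < 90:
                raise ValueError("bond tilts must be in [0, 90) degrees")

    @classmethod
    def from_p2t(cls, p2t: float, **kwargs) -> "SyntheticSpec":
        """Rigid-tilt spec whose P2t (and every P2b) equals ``p2t``."""
        theta = tilt_of_p2(p2t)
        return cls(bond_tilts_deg=(theta, theta, theta), **kwargs)

    # -- analytic ground truth ----------------------------------------------

    def p2b_truth(self) -> tuple[float, float, float]:
        return tuple(p2_of_tilt(t) for t in self.bond_tilts_deg)

    def p2t_truth(self) -> float:
        cz = sum(math.cos(math.radians(t)) for t in self.bond_tilts_deg)
        cl = sum(math.sin(math.radians(t)) for t in self.bond_tilts_deg)
        cos2 = cz * cz / (cz * cz + cl * cl)
        return 0.5 * (3 * cos2 - 1)

    def ground_truth(self) -> dict:
        return {
            "apl_A2": self.apl,
            "thickness_A": self.thickness,
            "p2b": dict(zip(("c1-c2", "c2-c3", "c3-c4"), self.p2b_truth())),
            "p2t": self.p2t_truth(),
            "D_cm2_s": self.d_cm2_s,
        }


def gen_bilayer_trajectory(
    spec: SyntheticSpec,
    tables: ForceFieldTables | None = None,
):
    """Generate (trajectory, system, ground_truth) for a synthetic bilayer."""
    tables = tables or default_forcefield()
    topo = lipid_topology(spec.species, protonated=spec.protonated,
                          tables=tables)
    n_leaf = spec.lipids_per_leaflet
    n_lip = 2 * n_leaf
    lx = ly = math.sqrt(spec.apl * n_leaf)
    head_clearance = 12.0
    lz = spec.thickness + 2 * (head_clearance + 8.0)
    if spec.thickness + 2 * head_clearance > lz:
        raise ValueError("thickness incompatible with box height")
    box = np.array([lx, ly, lz])
    z_mid = lz / 2

    rng = np.random.default_rng(spec.seed)
    nb = topo.n_beads
    n_beads = n_lip * nb

    # static intra-lipid z offsets (from midplane, upper leaflet)
    z_c1 = spec.thickness / 2
    tilts = np.radians(np.asarray(spec.bond_tilts_deg))
    dz_bond = BOND_LENGTH * np.cos(tilts)  # toward midplane
    dl_bond = BOND_LENGTH * np.sin(tilts)  # lateral
    head_z = {i: z_c1 + 4.0 + 1.5 * k
              for k, i in enumerate(topo.head_beads)}
    gly_z = z_c1 + 2.0

    # Brownian centers: step variance 2 D dt per axis
    d_a2_ns = spec.d_cm2_s / c.A2_PER_NS_TO_CM2_PER_S
    step_sd = math.sqrt(2 * d_a2_ns * spec.frame_interval_ns)
    nxg = int(math.ceil(math.sqrt(n_leaf)))
    centers0 = np.empty((n_lip, 2))
    for leaf in range(2):
        for i in range(n_leaf):
            ix, iy = divmod(i, nxg)
            centers0[leaf * n_leaf + i] = (
                (ix + 0.5) * lx / nxg, (iy + 0.5) * ly / nxg)
    steps = rng.normal(scale=step_sd, size=(spec.n_frames - 1, n_lip, 2)) \
        if step_sd > 0 else np.zeros((spec.n_frames - 1, n_lip, 2))
    centers = np.concatenate(
        [centers0[None], centers0[None] + np.cumsum(steps, axis=0)], axis=0)

    coords = np.zeros((spec.n_frames, n_beads, 3))
    tail_bead_ids = [list(t.beads) for t in topo.tails]
    n_tails = len(tail_bead_ids)
    # per frame, per lipid, per tail azimuth
    phis = rng.uniform(0, 2 * math.pi,
                       size=(spec.n_frames, n_lip, n_tails))

    for li in range(n_lip):
        sign = 1 if li < n_leaf else -1
        base = li * nb
        # heads and glycerol: fixed offsets above the C1 plane
        for bi in range(nb):
            if bi in head_z:
                coords[:, base + bi, 2] = z_mid + sign * head_z[bi]
            coords[:, base + bi, 0] = centers[:, li, 0]
            coords[:, base + bi, 1] = centers[:, li, 1]
        for bi in range(nb):
            in_tail = any(bi in t for t in tail_bead_ids)
            if not in_tail and bi not in head_z:
                coords[:, base + bi, 2] = z_mid + sign * gly_z
        for ti, beads in enumerate(tail_bead_ids):
            phi = phis[:, li, ti]
            cphi, sphi = np.cos(phi), np.sin(phi)
            # small lateral separation so the two tails do not coincide
            x0 = centers[:, li, 0] + (ti - (n_tails - 1) / 2) * 2.4
            y0 = centers[:, li, 1]
            z = np.full(spec.n_frames, z_mid + sign * z_c1)
            x, y = x0.copy(), y0.copy()
            coords[:, beads[0] + base, 0] = x
            coords[:, beads[0] + base, 1] = y
            coords[:, beads[0] + base, 2] = z
            for k in range(3):
                x = x + dl_bond[k] * cphi
                y = y + dl_bond[k] * sphi
                z = z - sign * dz_bond[k]
                coords[:, beads[k + 1] + base, 0] = x
                coords[:, beads[k + 1] + base, 1] = y
                coords[:, beads[k + 1] + base, 2] = z

    coords -= np.floor(coords / box) * box

    label = spec.species + ("+" if spec.protonated else "")
    system = System(
        coords=coords[0].copy(),
        velocities=np.zeros((n_beads, 3)),
        types=np.array([b.bead_type for _ in range(n_lip)
                        for b in topo.beads], dtype=object),
        charges=np.array([b.charge for _ in range(n_lip)
                          for b in topo.beads], float),
        masses=np.array([b.mass for _ in range(n_lip)
                         for b in topo.beads], float),
        mol_index=np.repeat(np.arange(n_lip), nb),
        species=[label] * n_lip,
        box=box.copy(),
        topologies={label: topo},
        leaflet=np.array([1] * n_leaf + [-1] * n_leaf),
    )
    traj = Trajectory(
        coords=coords,
        boxes=np.tile(box, (spec.n_frames, 1)),
        times=np.arange(spec.n_frames) * spec.frame_interval_ns,
        effective_time_factor=1.0,  # synthetic times are already effective
        wrapped=True,
        meta={"generator": "gen_bilayer_trajectory", "seed": spec.seed},
    )
    return traj, system, spec.ground_truth()


def gen_brownian(
    n_walkers: int,
    d_cm2_s: float,
    dt_ns: float,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """Independent 2-D Brownian walkers (Gaussian steps, variance 2 D dt
    per axis); D = 0 gives static walkers. Returned as a trajectory of
    single-bead molecules in a large box, times on the effective clock."""
    if d_cm2_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if n_frames < 2 or n_walkers < 1:
        raise ValueError("need >= 2 frames and >= 1 walker")
    rng = np.random.default_rng(seed)
    d_a2_ns = d_cm2_s / c.A2_PER_NS_TO_CM2_PER_S
    step_sd = math.sqrt(2 * d_a2_ns * dt_ns)
    start = rng.uniform(0, 100.0, size=(1, n_walkers, 2))
    if step_sd > 0:
        steps = rng.normal(scale=step_sd, size=(n_frames - 1, n_walkers, 2))
    else:
        steps = np.zeros((n_frames - 1, n_walkers, 2))
    xy = np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)
    coords = np.zeros((n_frames, n_walkers, 3))
    coords[:, :, :2] = xy
    # box far larger than any excursion: no wrapping to undo
    extent = float(np.abs(coords).max()) + 100.0
    return Trajectory(
        coords=coords + extent,  # keep everything positive
        boxes=np.tile([4 * extent, 4 * extent, 4 * extent], (n_frames, 1)),
        times=np.arange(n_frames) * dt_ns,
        effective_time_factor=1.0,
        wrapped=False,
        meta={"generator": "gen_brownian", "seed": seed, "D_cm2_s": d_cm2_s},
    )
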