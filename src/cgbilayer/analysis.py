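"""Bilayer characterization metrics.

Four quantities summarize structure and dynamics of a planar bilayer whose
normal is the z axis:

* **Area per lipid (APL)** — lateral box area divided by the number of
  lipids in one leaflet, per frame.
* **Hydrophobic thickness** — distance along z between the mean planes of
  the first tail beads (C1) of the two leaflets.
* **Second-rank order parameter** ``P2 = <(3 cos^2 theta - 1)/2>`` with
  theta the angle between a bond (or tail) vector and the bilayer normal:
  1 for perfect alignment, 0 for isotropic orientations, -0.5 for
  perpendicular. ``P2b`` is evaluated per consecutive tail bond
  (c1-c2, c2-c3, c3-c4), ``P2t`` on the C1->C4 end-to-end vector, both
  grouped by chain kind (saturated "pal" / unsaturated "ol") and species.
* **Lateral diffusion coefficient** — from the Einstein relation in two
  dimensions, MSD(t) = 4 D t, fitted over a configurable lag window on the
  effective-time axis.

All functions accept any :class:`~cgbilayer.trajectory.Trajectory`
(engine-produced or synthetic) plus the :class:`~cgbilayer.system.System`
that describes which beads belong to which lipid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as c
from .system import System
from .trajectory import Trajectory

__all__ = [
    "MetricsReport",
    "area_per_lipid",
    "hydrophobic_thickness",
    "p2",
    "p2_bond",
    "p2_tail",
    "msd_lateral",
    "lipid_lateral_msd",
    "fit_diffusion",
    "analyze_trajectory",
    "block_sem",
]

BOND_LABELS = ("c1-c2", "c2-c3", "c3-c4")


def block_sem(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean from block averages (correlation-robust)."""
    series = np.asarray(series, float)
    if len(series) < n_blocks:
        return float("nan")
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class SeriesStat:
    mean: float
    sd: float
    sem: float
    series: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "sem": self.sem}


def _series_stat(series: np.ndarray) -> SeriesStat:
    series = np.asarray(series, float)
    return SeriesStat(
        mean=float(series.mean()),
        sd=float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        sem=block_sem(series),
        series=series,
    )


# ---------------------------------------------------------------------------
# APL and thickness


def area_per_lipid(trajectory: Trajectory, lipids_per_leaflet: int) -> SeriesStat:
    """Per-frame Lx*Ly / lipids-per-leaflet (A^2), with mean, sd and block SEM."""
    if lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be positive")
    series = trajectory.boxes[:, 0] * trajectory.boxes[:, 1] / lipids_per_leaflet
    return _series_stat(series)


def _leaflet_sign(trajectory: Trajectory, system: System) -> np.ndarray:
    """Per-frame, per-lipid leaflet assignment (+1 upper / -1 lower).

    A lipid's leaflet is the side of the bilayer midplane its head beads
    sit on; the midplane is the mean z of all lipid beads in the frame.
    Stable across frames as long as no lipid flips.
    """
    lipid_mols = system.lipid_mols()
    if len(lipid_mols) == 0:
        raise ValueError("system contains no lipids")
    all_lipid = system.lipid_bead_indices("all")
    signs = np.empty((trajectory.n_frames, len(lipid_mols)), dtype=int)
    head_idx = [
        np.array([system.mol_slice(int(m)).start + i
                  for i in system.topologies[system.species[m]].head_beads])
        for m in lipid_mols
    ]
    for f in range(trajectory.n_frames):
        z = trajectory.coords[f, :, 2]
        midplane = z[all_lipid].mean()
        for li, idx in enumerate(head_idx):
            signs[f, li] = 1 if z[idx].mean() >= midplane else -1
    return signs


def hydrophobic_thickness(trajectory: Trajectory, system: System) -> SeriesStat:
    """Inter-leaflet distance between the mean C1 planes, per frame (A)."""
    lipid_mols = system.lipid_mols()
    signs = _leaflet_sign(trajectory, system)
    if not (np.any(signs == 1) and np.any(signs == -1)):
        raise ValueError("trajectory contains only one leaflet")
    c1_by_mol = [
        np.array([system.mol_slice(int(m)).start + i
                  for i in system.topologies[system.species[m]].c1_indices()])
        for m in lipid_mols
    ]
    series = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        z = trajectory.coords[f, :, 2]
        upper = [z[idx] for li, idx in enumerate(c1_by_mol) if signs[f, li] > 0]
        lower = [z[idx] for li, idx in enumerate(c1_by_mol) if signs[f, li] < 0]
        if not upper or not lower:
            raise ValueError(f"frame {f}: one leaflet is empty")
        series[f] = np.concatenate(upper).mean() - np.concatenate(lower).mean()
    return _series_stat(np.abs(series))


# ---------------------------------------------------------------------------
# order parameters


def p2(vectors: np.ndarray, normal=(0.0, 0.0, 1.0)) -> float:
    """Second-rank order parameter of a set of vectors vs. a reference axis."""
    v = np.asarray(vectors, float).reshape(-1, 3)
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    norm2 = np.einsum("ij,ij->i", v, v)
    if np.any(norm2 == 0):
        raise ValueError("zero-length vector in P2 input")
    cos2 = (v @ n) ** 2 / norm2
    return float((1.5 * cos2 - 0.5).mean())


def _tail_vectors(trajectory, system, pairs_of_tail):
    """Collect cos^2(theta) samples grouped by (species, chain, label).

    ``pairs_of_tail(tail)`` maps a topology tail to a list of
    (label, local_i, local_j) bead-index pairs defining the vectors.
    """
    groups: dict[tuple[str, str, str], list[np.ndarray]] = {}
    for m in system.lipid_mols():
        sp = system.species[m]
        topo = system.topologies[sp]
        base = system.mol_slice(int(m)).start
        for tail in topo.tails:
            for label, li, lj in pairs_of_tail(tail):
                i, j = base + li, base + lj
                d = trajectory.coords[:, j, :] - trajectory.coords[:, i, :]
                d -= np.round(d / trajectory.boxes) * trajectory.boxes
                norm2 = np.einsum("ij,ij->i", d, d)
                if np.any(norm2 == 0):
                    raise ValueError("zero-length bond vector")
                cos2 = d[:, 2] ** 2 / norm2
                groups.setdefault((sp, tail.kind, label), []).append(cos2)
    return groups


def _groups_to_frame(groups) -> pd.DataFrame:
    rows = []
    for (sp, kind, label), chunks in sorted(groups.items()):
        cos2 = np.concatenate(chunks)
        rows.append({
            "species": sp,
            "chain": kind,
            "bond": label,
            "p2": float((1.5 * cos2 - 0.5).mean()),
            "n_samples": len(cos2),
        })
    return pd.DataFrame(rows)


def p2_bond(trajectory: Trajectory, system: System) -> pd.DataFrame:
    """P2 of consecutive tail bonds c1-c2, c2-c3, c3-c4 per chain kind."""

    def pairs(tail):
        return [
            (BOND_LABELS[k], tail.beads[k], tail.beads[k + 1])
            for k in range(3)
        ]

    return _groups_to_frame(_tail_vectors(trajectory, system, pairs))


def p2_tail(trajectory: Trajectory, system: System) -> pd.DataFrame:
    """P2 of the C1->C4 end-to-end tail vector per chain kind."""

    def pairs(tail):
        return [("c1-c4", tail.beads[0], tail.beads[3])]

    df = _groups_to_frame(_tail_vectors(trajectory, system, pairs))
    return df.drop(columns=["bond"])


# ---------------------------------------------------------------------------
# diffusion


def msd_lateral(
    positions: np.ndarray,
    groups: np.ndarray | None = None,
    remove_drift: bool = True,
    max_lag_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Lateral MSD over lag index, averaged over walkers and time origins.

    Parameters
    ----------
    positions : (F, M, 2) unwrapped lateral positions.
    groups : (M,) optional group labels (e.g. leaflet of each lipid); the
        center-of-mass drift of each group is removed per frame before
        accumulation, and the MSD is rescaled by M_g/(M_g - 1) per group so
        that independent walkers remain unbiased.

    Returns (lag_indices, msd) with msd[0] = 0.
    """
    pos = np.asarray(positions, float)
    if pos.ndim != 3 or pos.shape[2] != 2:
        raise ValueError("positions must have shape (frames, walkers, 2)")
    n_frames, n_walk = pos.shape[:2]
    if n_frames < 2:
        raise ValueError("need at least 2 frames for an MSD")
    if groups is None:
        groups = np.zeros(n_walk, dtype=int)
    groups = np.asarray(groups)

    corrected = pos.copy()
    scale = np.ones(n_walk)
    if remove_drift:
        for g in np.unique(groups):
            sel = groups == g
            m_g = int(sel.sum())
            com = pos[:, sel, :].mean(axis=1, keepdims=True)
            corrected[:, sel, :] = pos[:, sel, :] - com
            if m_g > 1:
                scale[sel] = m_g / (m_g - 1.0)

    max_lag = max(1, int(np.floor(n_frames * max_lag_fraction)))
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        disp = corrected[lag:] - corrected[:-lag]  # (F-lag, M, 2)
        per_walker = (disp**2).sum(axis=2).mean(axis=0)  # (M,)
        msd[lag] = float((per_walker * scale).mean())
    return lags, msd


def lipid_lateral_msd(trajectory: Trajectory, system: System):
    """MSD of lipid centers of mass; returns (lag times in actual ns, msd A^2).

    Coordinates are unwrapped by nearest-image continuity and per-leaflet
    center-of-mass drift is removed.
    """
    lipid_mols = system.lipid_mols()
    unwrapped = trajectory.unwrapped()
    coms = np.empty((trajectory.n_frames, len(lipid_mols), 2))
    for li, m in enumerate(lipid_mols):
        sl = system.mol_slice(int(m))
        w = system.masses[sl]
        coms[:, li, :] = (
            (unwrapped[:, sl, :2] * w[None, :, None]).sum(axis=1) / w.sum()
        )
    leaflets = system.leaflet[lipid_mols] if system.leaflet is not None else None
    lags, msd = msd_lateral(coms, groups=leaflets)
    dt = float(np.mean(np.diff(trajectory.times)))
    return lags * dt, msd


@dataclass
class DiffusionFit:
    d_cm2_s: float
    stderr_cm2_s: float
    window: tuple[float, float]  # fraction of max lag used
    n_points: int
    slope_a2_per_ns: float

    def to_dict(self) -> dict:
        return {
            "D_cm2_s": self.d_cm2_s,
            "stderr_cm2_s": self.stderr_cm2_s,
            "fit_window": list(self.window),
            "n_points": self.n_points,
        }


def fit_diffusion(
    lag_times_ns: np.ndarray,
    msd_a2: np.ndarray,
    effective_time_factor: float = 1.0,
    window: tuple[float, float] = (0.1, 0.5),
    min_points: int = 10,
) -> DiffusionFit:
    """Weighted least-squares MSD slope over a lag window -> D in cm^2/s.

    Lag times are multiplied by the effective-time factor before fitting
    (CG dynamics run on an accelerated clock), so doubling the factor
    halves the fitted D. The default 10-50% window skips the short-lag
    regime (not yet diffusive for engine data) and the long-lag tail;
    within the window each lag is weighted by the number of independent
    intervals it averages over (~ (T - t)/t), since the variance of a
    time-origin-averaged MSD grows roughly linearly with the lag.
    """
    t = np.asarray(lag_times_ns, float) * effective_time_factor
    y = np.asarray(msd_a2, float)
    if len(t) != len(y):
        raise ValueError("lag and msd arrays differ in length")
    t_max = t.max()
    sel = (t >= window[0] * t_max) & (t <= window[1] * t_max) & (t > 0)
    if sel.sum() < min_points:
        raise ValueError(
            f"need >= {min_points} lag points in the fit window, "
            f"have {int(sel.sum())}"
        )
    tw, yw = t[sel], y[sel]
    span = t[-1] - t[0]
    w = np.maximum(span - tw, tw * 1e-3) / tw  # ~independent intervals
    A = np.column_stack([tw, np.ones_like(tw)])
    Aw = A * np.sqrt(w)[:, None]
    yw_w = yw * np.sqrt(w)
    coef, _, *_ = np.linalg.lstsq(Aw, yw_w, rcond=None)
    slope = float(coef[0])
    dof = len(tw) - 2
    if dof > 0:
        resid = yw - A @ coef
        s2 = float((w * resid**2).sum()) / dof
        cov = s2 * np.linalg.inv(Aw.T @ Aw)
        slope_se = math.sqrt(max(cov[0, 0], 0.0))
    else:
        slope_se = 0.0
    if slope < 0:
        warnings.warn("negative MSD slope; reporting D = 0", stacklevel=2)
        slope = 0.0
    d = slope / 4.0 * c.A2_PER_NS_TO_CM2_PER_S
    return DiffusionFit(
        d_cm2_s=d,
        stderr_cm2_s=slope_se / 4.0 * c.A2_PER_NS_TO_CM2_PER_S,
        window=window,
        n_points=int(sel.sum()),
        slope_a2_per_ns=slope,
    )


# ---------------------------------------------------------------------------
# full report


@dataclass
class MetricsReport:
    apl: SeriesStat
    thickness: SeriesStat
    p2b: pd.DataFrame
    p2t: pd.DataFrame
    diffusion: DiffusionFit
    lipids_per_leaflet: int
    effective_time_factor: float

    def __post_init__(self) -> None:
        if self.apl.mean <= 0 or self.thickness.mean <= 0:
            raise ValueError("APL and thickness must be positive")
        for df in (self.p2b, self.p2t):
            bad = (df["p2"] < -0.5 - 1e-9) | (df["p2"] > 1 + 1e-9)
            if bad.any():
                raise ValueError("P2 outside [-0.5, 1]")
        if self.diffusion.d_cm2_s < 0:
            raise ValueError("D must be non-negative")

    def to_dict(self) -> dict:
        return {
            "apl_A2": self.apl.to_dict(),
            "hydrophobic_thickness_A": self.thickness.to_dict(),
            "p2_bond": self.p2b.to_dict(orient="records"),
            "p2_tail": self.p2t.to_dict(orient="records"),
            "diffusion": self.diffusion.to_dict(),
            "lipids_per_leaflet": self.lipids_per_leaflet,
            "effective_time_factor": self.effective_time_factor,
        }


def analyze_trajectory(trajectory: Trajectory, system: System,
                       fit_window: tuple[float, float] = (0.1, 0.5)
                       ) -> MetricsReport:
    """Compute the full metric set for one trajectory."""
    n_leaf = int((np.asarray(system.leaflet)[system.lipid_mols()] > 0).sum())
    if n_leaf == 0:
        # fall back to per-frame assignment of the first frame
        n_leaf = int((_leaflet_sign(trajectory[0], system)[0] > 0).sum())
    lags_ns, msd = lipid_lateral_msd(trajectory, system)
    try:
        dfit = fit_diffusion(lags_ns, msd, trajectory.effective_time_factor,
                             window=fit_window)
    except ValueError:
        # short trajectory: fall back to every available positive lag
        warnings.warn("too few lags for the configured MSD window; "
                      "fitting over all lags", stacklevel=2)
        dfit = fit_diffusion(lags_ns, msd, trajectory.effective_time_factor,
                             window=(0.0, 1.0), min_points=3)
    return MetricsReport(
        apl=area_per_lipid(trajectory, n_leaf),
        thickness=hydrophobic_thickness(trajectory, system),
        p2b=p2_bond(trajectory, system),
        p2t=p2_tail(trajectory, system),
        diffusion=dfit,
        lipids_per_leaflet=n_leaf,
        effective_time_factor=trajectory.effective_time_factor,
    )
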