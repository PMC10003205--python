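"""Minimal coarse-grained MD engine for bilayer systems.

Potentials are MARTINI-style: Lennard-Jones 12-6 with the potential shifted
to zero at the cutoff, harmonic bonds, cosine-harmonic angles, and Ewald
electrostatics with a uniform relative dielectric. Integration is velocity
Verlet; temperature is controlled by a Nosé–Hoover thermostat and pressure
by weak-coupling box rescaling, semi-isotropic by default so the membrane
plane and the normal relax independently and the area per lipid is free to
equilibrate.

Sampled CG dynamics are faster than the underlying atomistic dynamics;
reported trajectory times carry an effective-time factor (default 4) that
analysis applies before fitting time-dependent quantities.

The engine is deliberately small: orthorhombic boxes, no constraints, no
virtual sites. Neighbor searching uses a periodic k-d tree with a Verlet
skin. First (bonded) and second (angle 1-3) neighbors are excluded from
nonbonded interactions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from . import constants as c
from .ewald import ewald_params, ewald_sum
from .forcefield import ForceFieldTables
from .system import System
from .trajectory import Trajectory

__all__ = [
    "EngineConfig",
    "EngineError",
    "energy_forces",
    "minimize",
    "integrate",
    "maxwell_velocities",
    "kinetic_energy",
    "temperature",
]

HARD_CORE = 1.0  # A; closer approaches are reported as bad contacts


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class EngineConfig:
    """Run parameters. Defaults follow the bilayer production protocol:

    20 fs step, 310 K, 1 bar, 12.5 A cutoffs for both van der Waals and
    real-space Coulomb, Ewald electrostatics, effective-time factor 4.
    """

    dt_fs: float = 20.0
    temperature: float = 310.0  # K
    pressure: float = 1.0  # bar
    thermostat: str = "nose-hoover"  # or "none"
    tau_t: float = 1.0  # ps
    barostat: str = "weak-coupling"  # or "none"
    pressure_mode: str = "semi-isotropic"  # or "isotropic"
    tau_p: float = 4.0  # ps
    compressibility: float = 4.5e-5  # bar^-1
    r_vdw: float = 12.5  # A
    coulomb: str = "ewald"  # "ewald" or "none"
    r_coul: float = 12.5  # A
    ewald_accuracy: float = 1e-4
    effective_time_factor: float = c.EFFECTIVE_TIME_FACTOR
    seed: int = 0
    skin: float = 2.0  # A, Verlet skin
    max_box_scale: float = 1.02  # per-step clamp on barostat scaling

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("time step must be positive")
        if self.effective_time_factor <= 0:
            raise ValueError("effective-time factor must be positive")
        if self.thermostat not in ("nose-hoover", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.barostat not in ("weak-coupling", "none"):
            raise ValueError(f"unknown barostat {self.barostat!r}")
        if self.pressure_mode not in ("semi-isotropic", "isotropic"):
            raise ValueError(f"unknown pressure mode {self.pressure_mode!r}")
        if self.coulomb not in ("ewald", "none"):
            raise ValueError(f"unknown coulomb method {self.coulomb!r}")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3

    def check_box(self, box: np.ndarray) -> None:
        rmax = max(self.r_vdw, self.r_coul if self.coulomb != "none" else 0.0)
        if rmax > min(box) / 2 + 1e-9:
            raise EngineError(
                f"cutoff {rmax} A exceeds half the smallest box length "
                f"({min(box) / 2:.2f} A)"
            )


# ---------------------------------------------------------------------------
# force evaluation


class _Evaluator:
    """Caches per-system tables (type codes, pair parameters, exclusions)."""

    def __init__(self, system: System, tables: ForceFieldTables,
                 config: EngineConfig):
        self.config = config
        self.tables = tables
        types = sorted(set(system.types.tolist()))
        code = {t: k for k, t in enumerate(types)}
        self.codes = np.array([code[t] for t in system.types], dtype=int)
        nt = len(types)
        self.eps = np.zeros((nt, nt))
        self.sig = np.zeros((nt, nt))
        for a in types:
            for b in types:
                e, s = tables.lookup(a, b)
                self.eps[code[a], code[b]] = e
                self.sig[code[a], code[b]] = s
        rc = config.r_vdw
        sr6c = (self.sig / rc) ** 6
        self.shift = 4 * self.eps * (sr6c**2 - sr6c)  # V(rc), subtracted

        (self.bond_ij, self.bond_r0, self.bond_k,
         self.angle_ijk, self.angle_t0, self.angle_k) = system.bonded_arrays()

        # nonbonded exclusions: 1-2 and 1-3
        excl: set[tuple[int, int]] = set()
        for i, j in self.bond_ij:
            excl.add((min(i, j), max(i, j)))
        for i, j, k in self.angle_ijk:
            excl.add((min(i, k), max(i, k)))
        self.excluded = np.array(sorted(excl), dtype=int).reshape(-1, 2)
        n = system.n_beads
        self._excl_keys = (
            self.excluded[:, 0] * n + self.excluded[:, 1]
            if len(self.excluded)
            else np.empty(0, dtype=int)
        )
        self.n = n
        self.charged = bool(np.any(system.charges != 0)) and config.coulomb == "ewald"
        self._pairs: np.ndarray | None = None
        self._ref_coords: np.ndarray | None = None
        self._ref_box: np.ndarray | None = None

    # -- neighbor list -------------------------------------------------------

    def _build_pairs(self, system: System) -> None:
        box = system.box
        self.config.check_box(box)
        wrapped = system.coords - np.floor(system.coords / box) * box
        # guard against coordinates landing exactly on the box edge
        wrapped = np.where(wrapped >= box, wrapped - box, wrapped)
        rmax = max(self.config.r_vdw,
                   self.config.r_coul if self.charged else 0.0)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(rmax + self.config.skin, output_type="ndarray")
        if len(pairs):
            keys = pairs[:, 0] * self.n + pairs[:, 1]
            keep = ~np.isin(keys, self._excl_keys, assume_unique=False)
            pairs = pairs[keep]
        self._pairs = pairs
        if self.charged and len(pairs):
            q = system.charges
            self._pairs_charged = pairs[
                (q[pairs[:, 0]] != 0) & (q[pairs[:, 1]] != 0)]
        else:
            self._pairs_charged = pairs[:0]
        self._ref_coords = system.coords.copy()
        self._ref_box = box.copy()

    def pairs(self, system: System) -> np.ndarray:
        if self._pairs is None or self._ref_box is None:
            self._build_pairs(system)
        else:
            if not np.array_equal(self._ref_box, system.box):
                self._build_pairs(system)
            else:
                disp = system.coords - self._ref_coords
                disp -= np.round(disp / system.box) * system.box
                if np.max(np.abs(disp)) > self.config.skin / 2:
                    self._build_pairs(system)
        return self._pairs

    # -- energy and forces ---------------------------------------------------

    def evaluate(self, system: System, warn_contacts: bool = False):
        """Potential energy, forces and diagonal virial.

        Returns (energy, forces (N,3), virial (3,), components dict).
        """
        coords, box = system.coords, system.box
        forces = np.zeros_like(coords)
        virial = np.zeros(3)
        comp: dict[str, float] = {}

        pairs = self.pairs(system)
        rc = self.config.r_vdw
        e_lj = 0.0
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d = coords[i] - coords[j]
            d -= np.round(d / box) * box
            r2 = np.einsum("ij,ij->i", d, d)
            inside = r2 < rc * rc
            i, j, d, r2 = i[inside], j[inside], d[inside], r2[inside]
            if warn_contacts and len(r2) and r2.min() < HARD_CORE**2:
                warnings.warn(
                    f"bad contact: minimum bead separation "
                    f"{math.sqrt(r2.min()):.2f} A < {HARD_CORE} A",
                    stacklevel=2,
                )
            eps = self.eps[self.codes[i], self.codes[j]]
            sig = self.sig[self.codes[i], self.codes[j]]
            shift = self.shift[self.codes[i], self.codes[j]]
            sr2 = sig * sig / r2
            sr6 = sr2**3
            sr12 = sr6**2
            e_lj = float((4 * eps * (sr12 - sr6) - shift).sum())
            fmag = 24 * eps * (2 * sr12 - sr6) / r2
            fvec = fmag[:, None] * d
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)
            virial += np.einsum("ij,ij->j", fvec, d)
        comp["lj"] = e_lj

        e_bond = 0.0
        if len(self.bond_ij):
            i, j = self.bond_ij[:, 0], self.bond_ij[:, 1]
            d = coords[i] - coords[j]
            d -= np.round(d / box) * box
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            dr = r - self.bond_r0
            e_bond = float((0.5 * self.bond_k * dr**2).sum())
            fmag = -self.bond_k * dr / r
            fvec = fmag[:, None] * d
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)
            virial += np.einsum("ij,ij->j", fvec, d)
        comp["bond"] = e_bond

        e_angle = 0.0
        if len(self.angle_ijk):
            ii, jj, kk = (self.angle_ijk[:, 0], self.angle_ijk[:, 1],
                          self.angle_ijk[:, 2])
            u = coords[ii] - coords[jj]
            u -= np.round(u / box) * box
            v = coords[kk] - coords[jj]
            v -= np.round(v / box) * box
            nu = np.sqrt(np.einsum("ij,ij->i", u, u))
            nv = np.sqrt(np.einsum("ij,ij->i", v, v))
            cos_t = np.einsum("ij,ij->i", u, v) / (nu * nv)
            cos_t = np.clip(cos_t, -1.0, 1.0)
            cos_0 = np.cos(np.radians(self.angle_t0))
            diff = cos_t - cos_0
            e_angle = float((0.5 * self.angle_k * diff**2).sum())
            dEdcos = self.angle_k * diff
            gi = (v / (nu * nv)[:, None] - cos_t[:, None] * u / (nu**2)[:, None])
            gk = (u / (nu * nv)[:, None] - cos_t[:, None] * v / (nv**2)[:, None])
            fi = -dEdcos[:, None] * gi
            fk = -dEdcos[:, None] * gk
            np.add.at(forces, ii, fi)
            np.add.at(forces, kk, fk)
            np.add.at(forces, jj, -(fi + fk))
            virial += np.einsum("ij,ij->j", fi, u) + np.einsum("ij,ij->j", fk, v)
        comp["angle"] = e_angle

        e_coul = 0.0
        if self.charged:
            prefactor = self.tables.coulomb_constant / self.tables.relative_dielectric
            params = ewald_params(box, self.config.r_coul,
                                  self.config.ewald_accuracy)
            e_coul, f_coul, w_coul = ewald_sum(
                coords, system.charges, box, prefactor, self.config.r_coul,
                params, pair_ij=self._pairs_charged,
                excluded_ij=self.excluded,
            )
            forces += f_coul
            virial += w_coul
        comp["coulomb"] = e_coul

        energy = e_lj + e_bond + e_angle + e_coul
        if not np.isfinite(energy):
            raise EngineError("non-finite potential energy (diverged system?)")
        return energy, forces, virial, comp


def energy_forces(system: System, tables: ForceFieldTables,
                  config: EngineConfig | None = None):
    """Potential energy (kJ/mol) and per-bead forces (kJ/mol/A)."""
    config = config or EngineConfig()
    ev = _Evaluator(system, tables, config)
    e, f, _, _ = ev.evaluate(system, warn_contacts=True)
    return e, f


# ---------------------------------------------------------------------------
# kinetics


def kinetic_energy(system: System) -> float:
    v2 = np.einsum("ij,ij->i", system.velocities, system.velocities)
    return 0.5 * c.KE_CONV * float((system.masses * v2).sum())


def n_dof(system: System) -> int:
    # total momentum is conserved and removed at initialization
    return 3 * system.n_beads - 3


def temperature(system: System) -> float:
    return 2 * kinetic_energy(system) / (n_dof(system) * c.KB)


def maxwell_velocities(system: System, temperature_k: float, seed: int) -> None:
    """Draw Maxwell-Boltzmann velocities in place; zero net momentum, then
    rescale to the exact target temperature."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(c.KB * temperature_k / (c.KE_CONV * system.masses))
    v = rng.normal(size=(system.n_beads, 3)) * sigma[:, None]
    p = (system.masses[:, None] * v).sum(axis=0) / system.masses.sum()
    v -= p[None, :]
    system.velocities = v
    t_now = temperature(system)
    if t_now > 0:
        system.velocities *= math.sqrt(temperature_k / t_now)


def _pressure_diag(system: System, virial: np.ndarray) -> np.ndarray:
    """Diagonal of the pressure tensor, in bar."""
    v2 = system.velocities**2
    kin = c.KE_CONV * (system.masses[:, None] * v2).sum(axis=0)
    volume = float(np.prod(system.box))
    p_internal = (kin + virial) / volume  # kJ/mol/A^3
    return p_internal / c.BAR_TO_KJMOL_A3


# ---------------------------------------------------------------------------
# minimization


def minimize(system: System, tables: ForceFieldTables,
             config: EngineConfig | None = None, max_iter: int = 500,
             ftol: float = 1e-8) -> System:
    """Energy-minimize to remove bad contacts (L-BFGS on bead coordinates).

    Returns a new System; the result never has higher energy than the input.
    """
    config = config or EngineConfig()
    work = system.copy()
    ev = _Evaluator(work, tables, config)
    shape = work.coords.shape

    def fun(x: np.ndarray):
        work.coords = x.reshape(shape)
        ev._build_pairs(work)  # geometry changes quickly during minimization
        e, f, _, _ = ev.evaluate(work)
        return e, -f.ravel()

    e0, _, _, _ = ev.evaluate(work)
    res = _scipy_minimize(
        fun, system.coords.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": ftol},
    )
    out = system.copy()
    if res.fun <= e0:
        out.coords = res.x.reshape(shape)
        out.wrap()
    return out


# ---------------------------------------------------------------------------
# integration


def integrate(
    system: System,
    tables: ForceFieldTables,
    config: EngineConfig | None = None,
    n_steps: int = 1000,
    traj_stride: int = 100,
    log_stride: int = 100,
    initialize_velocities: bool = True,
):
    """Velocity-Verlet NVT/NPT (or NVE) run.

    Returns (trajectory, final_system, log) where log is a list of dicts
    (step, time_ps, potential, kinetic, temperature, pressures, box).
    Frames carry actual times; the trajectory records the configured
    effective-time factor. Identical seeds give identical trajectories.
    """
    config = config or EngineConfig()
    work = system.copy()
    work.wrap()
    config.check_box(work.box)
    if initialize_velocities and config.thermostat != "none":
        maxwell_velocities(work, config.temperature, config.seed)

    ev = _Evaluator(work, tables, config)
    dt = config.dt_ps
    nf = n_dof(work)
    kbt = c.KB * config.temperature
    q_nh = nf * kbt * config.tau_t**2  # Nose-Hoover "mass", kJ/mol ps^2
    xi = 0.0

    energy, forces, virial, _ = ev.evaluate(work)
    acc = c.ACC_CONV * forces / work.masses[:, None]

    frames, boxes, times = [work.coords.copy()], [work.box.copy()], [0.0]
    log: list[dict] = []

    def log_state(step: int) -> None:
        p_diag = _pressure_diag(work, virial)
        log.append({
            "step": step,
            "time_ps": step * dt,
            "potential": energy,
            "kinetic": kinetic_energy(work),
            "temperature": temperature(work),
            "p_lateral": 0.5 * (p_diag[0] + p_diag[1]),
            "p_normal": p_diag[2],
            "box_x": work.box[0], "box_y": work.box[1], "box_z": work.box[2],
        })

    log_state(0)
    for step in range(1, n_steps + 1):
        if config.thermostat == "nose-hoover":
            work.velocities = (work.velocities + 0.5 * dt * acc) / (
                1.0 + 0.5 * dt * xi)
        else:
            work.velocities = work.velocities + 0.5 * dt * acc
        work.coords = work.coords + dt * work.velocities

        energy, forces, virial, _ = ev.evaluate(work)
        if not np.isfinite(energy) or not np.all(np.isfinite(forces)):
            raise EngineError(f"divergence at step {step}")
        acc = c.ACC_CONV * forces / work.masses[:, None]

        if config.thermostat == "nose-hoover":
            xi += dt * (2 * kinetic_energy(work) - nf * kbt) / q_nh
            work.velocities = (work.velocities + 0.5 * dt * acc) / (
                1.0 + 0.5 * dt * xi)
        else:
            work.velocities = work.velocities + 0.5 * dt * acc

        if config.barostat == "weak-coupling":
            p_diag = _pressure_diag(work, virial)
            beta = config.compressibility
            lo, hi = 1.0 / config.max_box_scale, config.max_box_scale
            if config.pressure_mode == "semi-isotropic":
                p_lat = 0.5 * (p_diag[0] + p_diag[1])
                mu_lat = (1.0 - beta * dt / config.tau_p
                          * (config.pressure - p_lat)) ** (1.0 / 3.0)
                mu_z = (1.0 - beta * dt / config.tau_p
                        * (config.pressure - p_diag[2])) ** (1.0 / 3.0)
                mu = np.array([mu_lat, mu_lat, mu_z])
            else:
                p_iso = p_diag.mean()
                mu_iso = (1.0 - beta * dt / config.tau_p
                          * (config.pressure - p_iso)) ** (1.0 / 3.0)
                mu = np.full(3, mu_iso)
            mu = np.clip(mu, lo, hi)
            work.box = work.box * mu
            work.coords = work.coords * mu[None, :]

        if step % traj_stride == 0:
            wrapped = work.coords - np.floor(work.coords / work.box) * work.box
            frames.append(wrapped)
            boxes.append(work.box.copy())
            times.append(step * dt)
        if step % log_stride == 0:
            log_state(step)

    traj = Trajectory(
        coords=np.array(frames),
        boxes=np.array(boxes),
        times=np.array(times) / c.PS_PER_NS,
        effective_time_factor=config.effective_time_factor,
        wrapped=True,
        meta={"dt_fs": config.dt_fs, "n_steps": n_steps,
              "traj_stride": traj_stride, "seed": config.seed},
    )
    work.wrap()
    return traj, work, log


# the production protocol runs NPT; NVE is the thermostat="none",
# barostat="none" corner used by conservation tests
integrate_nvt_npt = integrate
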