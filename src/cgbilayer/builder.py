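"""Initial-configuration builder: bilayer lattice, solvent, counterions.

Bilayers are assembled directly in the bilayer state: each leaflet is a
jittered square lattice of lipids with heads outward and tails toward the
midplane, mirror-symmetric species counts across leaflets, solvent slabs
above and below, and (for protonated systems) one Cl- bead per unit of
lipid charge replacing a water bead.

The nine study compositions (pure POPC, three pure ISUCA-derived bilayers,
three 50:50 mixtures, and the 90:10 mixture in neutral and protonated
form) are available by name in :data:`SYSTEM_REGISTRY`; all of them carry
116 lipids (58 per leaflet) and 1840 solvent beads of which 30% are
antifreeze particles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import (
    ForceFieldTables,
    LipidTopology,
    default_forcefield,
    lipid_topology,
)
from .system import System

__all__ = [
    "Composition",
    "BuildError",
    "SYSTEM_REGISTRY",
    "build_bilayer",
    "solvate",
    "add_counterions",
    "build_named_system",
]

MIN_LATTICE_SPACING = 6.0  # A, below this the leaflet lattice is too crowded
SOLVENT_MIN_SPACING = 3.5  # A
SOLVENT_LIPID_GAP = 3.2  # A, clearance between solvent sites and lipid beads


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class Composition:
    """Per-leaflet lipid counts plus solvent content.

    Species keys ending in ``+`` denote the protonated form of an
    ISUCA-derived lipid. Counts are per leaflet; the bilayer is
    mirror-symmetric.
    """

    leaflet_counts: dict  # species -> count per leaflet
    n_water_beads: int = 1840
    antifreeze_fraction: float = 0.30

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.leaflet_counts.values()):
            raise BuildError("lipid counts must be non-negative")
        if not 0.0 <= self.antifreeze_fraction <= 1.0:
            raise BuildError("antifreeze fraction must be in [0, 1]")
        if self.n_water_beads < 0:
            raise BuildError("water bead count must be non-negative")

    @property
    def lipids_per_leaflet(self) -> int:
        return sum(self.leaflet_counts.values())

    @property
    def total_lipids(self) -> int:
        return 2 * self.lipids_per_leaflet

    @property
    def waters_per_lipid(self) -> float:
        """Real water molecules per lipid (each solvent bead maps 4 waters)."""
        from .constants import REAL_WATERS_PER_BEAD

        return REAL_WATERS_PER_BEAD * self.n_water_beads / self.total_lipids

    def species_list(self):
        """(species, protonated) pairs expanded to per-leaflet counts."""
        out = []
        for key, count in self.leaflet_counts.items():
            protonated = key.endswith("+")
            species = key[:-1] if protonated else key
            out.extend([(species, protonated)] * count)
        return out


# Study systems: label -> (per-leaflet counts, box dimensions in A).
# The pure-POPC lateral box is the 62.4 x 62.4 A surface of its final
# configuration; the normal dimension matches the other pure bilayers.
SYSTEM_REGISTRY: dict[str, tuple[dict, tuple[float, float, float]]] = {
    "POPC": ({"POPC": 58}, (62.4, 62.4, 90.0)),
    "ISUCA-2 Pal": ({"ISUCA-2 Pal": 58}, (63.8, 63.9, 90.0)),
    "ISUCA-2 Ol": ({"ISUCA-2 Ol": 58}, (65.1, 65.1, 87.9)),
    "ISUCA-Pal Ol": ({"ISUCA-Pal-Ol": 58}, (64.3, 64.3, 89.5)),
    "50:50 POPC/ISUCA-2 Pal": (
        {"POPC": 29, "ISUCA-2 Pal": 29}, (64.3, 63.4, 91.9)),
    "50:50 POPC/ISUCA-2 Ol": (
        {"POPC": 29, "ISUCA-2 Ol": 29}, (64.3, 63.4, 91.9)),
    "50:50 POPC/ISUCA-Pal-Ol": (
        {"POPC": 29, "ISUCA-Pal-Ol": 29}, (64.3, 63.4, 91.9)),
    "90:10 POPC/ISUCA-Pal-Ol": (
        {"POPC": 52, "ISUCA-Pal-Ol": 6}, (64.3, 63.5, 92.0)),
    "90:10 POPC/ISUCA+-Pal-Ol": (
        {"POPC": 52, "ISUCA-Pal-Ol+": 6}, (64.4, 63.5, 91.9)),
}


# -- intra-lipid template geometry ------------------------------------------
# z offsets from the bilayer midplane for an upper-leaflet lipid; the lower
# leaflet is the mirror image. Tails zig-zag toward the midplane.

_TAIL_Z = (10.4, 7.4, 4.4, 1.4)
_TAIL_XZIG = 1.5
_HEAD_Z = {
    "GL1": (-1.0, 0.0, 12.9),
    "GL2": (1.0, 0.0, 12.9),
    "PO4": (0.0, 0.5, 16.1),
    "NC3": (0.0, 1.0, 19.3),
    "IM1": (0.0, 0.5, 15.5),
    "IM2": (-1.2, 0.9, 17.9),
    "IM3": (1.2, 0.9, 17.9),
}


def _lipid_template(topo: LipidTopology) -> np.ndarray:
    """Canonical upper-leaflet coordinates (n_beads, 3), midplane at z=0."""
    coords = np.zeros((topo.n_beads, 3))
    placed = np.zeros(topo.n_beads, dtype=bool)
    for b_idx, bead in enumerate(topo.beads):
        if bead.name in _HEAD_Z:
            coords[b_idx] = _HEAD_Z[bead.name]
            placed[b_idx] = True
    for t_idx, tail in enumerate(topo.tails):
        x0 = -1.0 if t_idx == 0 else 1.0
        for k, b_idx in enumerate(tail.beads):
            coords[b_idx] = (
                x0 + (_TAIL_XZIG if k % 2 else 0.0),
                0.0,
                _TAIL_Z[k],
            )
            placed[b_idx] = True
    if not placed.all():
        missing = [topo.beads[i].name for i in np.nonzero(~placed)[0]]
        raise BuildError(f"no template position for beads {missing}")
    return coords


def _lipid_z_extent() -> float:
    return max(z for _, _, z in _HEAD_Z.values())


def build_bilayer(
    composition: Composition,
    box: tuple[float, float, float],
    seed: int = 0,
    tables: ForceFieldTables | None = None,
) -> System:
    """Assemble two mirror-symmetric leaflets on jittered square lattices.

    Species are randomly distributed over lattice sites within each leaflet
    (independently per leaflet, same counts). Velocities are zero; the
    engine assigns a Maxwell-Boltzmann distribution at run start.
    """
    tables = tables or default_forcefield()
    box = np.asarray(box, float)
    if np.any(box <= 0):
        raise BuildError("box lengths must be positive")
    n_leaf = composition.lipids_per_leaflet
    if n_leaf == 0:
        raise BuildError("composition contains no lipids")

    nx = int(math.ceil(math.sqrt(n_leaf)))
    ny = int(math.ceil(n_leaf / nx))
    sx, sy = box[0] / nx, box[1] / ny
    if min(sx, sy) < MIN_LATTICE_SPACING:
        raise BuildError(
            f"box too small: lattice spacing {min(sx, sy):.2f} A < "
            f"{MIN_LATTICE_SPACING} A for {n_leaf} lipids per leaflet"
        )
    z_mid = box[2] / 2
    if _lipid_z_extent() * 2 + 4 > box[2]:
        raise BuildError("box too short along the normal for a bilayer")

    rng = np.random.default_rng(seed)
    topo_cache: dict[tuple[str, bool], LipidTopology] = {}
    template_cache: dict[tuple[str, bool], np.ndarray] = {}

    coords_list, types, charges, masses, mol_index, species, leaflet = (
        [], [], [], [], [], [], [])
    mol = 0
    for sign in (+1, -1):
        entries = composition.species_list()
        rng.shuffle(entries)
        sites = [(ix, iy) for ix in range(nx) for iy in range(ny)][:n_leaf]
        for (sp, prot), (ix, iy) in zip(entries, sites):
            key = (sp, prot)
            if key not in topo_cache:
                topo_cache[key] = lipid_topology(sp, protonated=prot,
                                                 tables=tables)
                template_cache[key] = _lipid_template(topo_cache[key])
            topo = topo_cache[key]
            tmpl = template_cache[key].copy()
            tmpl[:, 2] *= sign
            # random in-plane rotation + jitter decorrelate the lattice
            phi = rng.uniform(0, 2 * math.pi)
            cphi, sphi = math.cos(phi), math.sin(phi)
            x, y = tmpl[:, 0].copy(), tmpl[:, 1].copy()
            tmpl[:, 0] = cphi * x - sphi * y
            tmpl[:, 1] = sphi * x + cphi * y
            origin = np.array([
                (ix + 0.5) * sx + rng.uniform(-0.3, 0.3),
                (iy + 0.5) * sy + rng.uniform(-0.3, 0.3),
                z_mid,
            ])
            pos = tmpl + origin
            coords_list.append(pos)
            types.extend(b.bead_type for b in topo.beads)
            charges.extend(b.charge for b in topo.beads)
            masses.extend(b.mass for b in topo.beads)
            mol_index.extend([mol] * topo.n_beads)
            label = sp + ("+" if prot else "")
            species.append(label)
            leaflet.append(sign)
            mol += 1

    topologies = {
        (sp + ("+" if prot else "")): topo
        for (sp, prot), topo in topo_cache.items()
    }
    system = System(
        coords=np.vstack(coords_list),
        velocities=np.zeros((sum(len(x) for x in coords_list), 3)),
        types=np.array(types, dtype=object),
        charges=np.array(charges, float),
        masses=np.array(masses, float),
        mol_index=np.array(mol_index, int),
        species=species,
        box=box,
        topologies=topologies,
        leaflet=np.array(leaflet, int),
    )
    system.wrap()
    _check_overlaps(system)
    return system


def _check_overlaps(system: System, tol: float = 1.8) -> None:
    wrapped = system.coords - np.floor(system.coords / system.box) * system.box
    wrapped = np.where(wrapped >= system.box, wrapped - system.box, wrapped)
    tree = cKDTree(wrapped, boxsize=system.box)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if len(pairs):
        # intra-molecular contacts are governed by bonds, not the lattice
        inter = pairs[system.mol_index[pairs[:, 0]]
                      != system.mol_index[pairs[:, 1]]]
        if len(inter):
            raise BuildError(
                f"{len(inter)} inter-molecular bead pairs closer than {tol} A "
                "in the initial configuration"
            )


def solvate(
    system: System,
    n_water_beads: int,
    antifreeze_fraction: float,
    seed: int = 0,
    tables: ForceFieldTables | None = None,
) -> System:
    """Add solvent beads in the slabs above and below the bilayer.

    Exactly ``n_water_beads`` beads are placed on a jittered grid clear of
    lipid beads; ``round(antifreeze_fraction * n)`` of them are typed as
    antifreeze particles, distributed uniformly at random.
    """
    tables = tables or default_forcefield()
    if not 0.0 <= antifreeze_fraction <= 1.0:
        raise BuildError("antifreeze fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    box = system.box
    lipid_z = system.coords[:, 2]
    z_lo = float(lipid_z.min()) - SOLVENT_LIPID_GAP
    z_hi = float(lipid_z.max()) + SOLVENT_LIPID_GAP
    heights = [("below", 0.0, max(z_lo, 0.0)), ("above", min(z_hi, box[2]), box[2])]
    total_h = sum(b - a for _, a, b in heights)
    if total_h <= 0:
        raise BuildError("no solvent volume left outside the bilayer")
    volume = box[0] * box[1] * total_h
    spacing0 = (volume / max(n_water_beads, 1)) ** (1.0 / 3.0)
    if spacing0 < SOLVENT_MIN_SPACING:
        raise BuildError(
            f"insufficient volume: solvent spacing {spacing0:.2f} A < "
            f"{SOLVENT_MIN_SPACING} A"
        )

    wrapped = system.coords - np.floor(system.coords / box) * box
    wrapped = np.where(wrapped >= box, wrapped - box, wrapped)
    tree = cKDTree(wrapped, boxsize=box)

    # densify the grid until enough lipid-free sites exist (rounding and the
    # clearance zone eat into the nominal capacity)
    sites_arr = np.empty((0, 3))
    for shrink in (1.0, 0.9, 0.8, 0.72, 0.65):
        spacing = max(spacing0 * shrink, SOLVENT_MIN_SPACING)
        nx = max(1, int(round(box[0] / spacing)))
        ny = max(1, int(round(box[1] / spacing)))
        sites = []
        for _, a, b in heights:
            h = b - a
            nz = max(1, int(round(h / spacing))) if h > spacing / 2 else 0
            for iz in range(nz):
                z = a + (iz + 0.5) * h / nz
                for ix in range(nx):
                    for iy in range(ny):
                        sites.append((
                            (ix + 0.5) * box[0] / nx,
                            (iy + 0.5) * box[1] / ny,
                            z,
                        ))
        if not sites:
            continue
        cand = np.array(sites)
        cand += rng.uniform(-0.35, 0.35, size=cand.shape)
        cand[:, 2] = np.clip(cand[:, 2], 0.0, box[2] - 1e-9)
        near = tree.query_ball_point(np.mod(cand, box), r=SOLVENT_LIPID_GAP)
        cand = cand[np.array([len(nb) == 0 for nb in near])]
        if len(cand) >= n_water_beads:
            sites_arr = cand
            break
        if spacing <= SOLVENT_MIN_SPACING:
            break
    if len(sites_arr) < n_water_beads:
        raise BuildError(
            f"insufficient volume: only {len(sites_arr)} solvent sites for "
            f"{n_water_beads} beads"
        )
    chosen = sites_arr[rng.choice(len(sites_arr), size=n_water_beads,
                                  replace=False)]

    n_af = int(round(antifreeze_fraction * n_water_beads))
    roles = np.array(["water"] * n_water_beads, dtype=object)
    roles[rng.choice(n_water_beads, size=n_af, replace=False)] = "antifreeze"

    water = tables.solvent["water"]
    anti = tables.solvent["antifreeze"]
    out = system.copy()
    mol0 = out.n_molecules
    new_types, new_charges, new_masses, new_mols, new_species = [], [], [], [], []
    for k, role in enumerate(roles):
        spec = anti if role == "antifreeze" else water
        new_types.append(spec.bead_type)
        new_charges.append(spec.charge)
        new_masses.append(tables.mass(spec.bead_type))
        new_mols.append(mol0 + k)
        new_species.append(spec.name)
    out.coords = np.vstack([out.coords, chosen])
    out.velocities = np.vstack([out.velocities, np.zeros((n_water_beads, 3))])
    out.types = np.concatenate([out.types, np.array(new_types, dtype=object)])
    out.charges = np.concatenate([out.charges, np.array(new_charges, float)])
    out.masses = np.concatenate([out.masses, np.array(new_masses, float)])
    out.mol_index = np.concatenate([out.mol_index, np.array(new_mols, int)])
    out.species = out.species + new_species
    out.leaflet = np.concatenate([out.leaflet, np.zeros(n_water_beads, int)])
    out.wrap()
    return out


def add_counterions(
    system: System,
    seed: int = 0,
    tables: ForceFieldTables | None = None,
) -> System:
    """Neutralize by replacing random water beads with monovalent counterions.

    A neutral system is returned unchanged (with a warning); a system with
    more charge than available water beads is an error.
    """
    tables = tables or default_forcefield()
    q = system.net_charge
    if q == 0:
        warnings.warn("add_counterions called on a neutral system; no-op",
                      stacklevel=2)
        return system.copy()
    water = tables.solvent["water"]
    ion = tables.solvent["counterion"]
    if (q > 0) != (ion.charge < 0):
        raise BuildError(
            f"counterion charge {ion.charge} cannot neutralize net charge {q}"
        )
    n_ions = abs(q)
    water_mols = [m for m, sp in enumerate(system.species) if sp == water.name]
    if len(water_mols) < n_ions:
        raise BuildError(
            f"need {n_ions} counterions but only {len(water_mols)} water beads"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(water_mols, size=n_ions, replace=False)
    out = system.copy()
    for m in chosen:
        sl = out.mol_slice(int(m))
        out.types[sl] = ion.bead_type
        out.charges[sl] = ion.charge
        out.masses[sl] = tables.mass(ion.bead_type)
        out.species[int(m)] = ion.name
    assert out.net_charge == 0
    return out


def build_named_system(
    name: str,
    seed: int = 0,
    tables: ForceFieldTables | None = None,
) -> System:
    """Build, solvate and (if needed) neutralize one of the study systems."""
    tables = tables or default_forcefield()
    if name not in SYSTEM_REGISTRY:
        raise BuildError(
            f"unknown system {name!r}; available: {sorted(SYSTEM_REGISTRY)}"
        )
    counts, box = SYSTEM_REGISTRY[name]
    comp = Composition(leaflet_counts=counts)
    system = build_bilayer(comp, box, seed=seed, tables=tables)
    system = solvate(system, comp.n_water_beads, comp.antifreeze_fraction,
                     seed=seed + 1, tables=tables)
    if system.net_charge != 0:
        system = add_counterions(system, seed=seed + 2, tables=tables)
    return system
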