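"""In-memory representation of a simulation system.

A :class:`System` is a flat array-of-beads view (coordinates, velocities,
types, charges, masses) plus molecule bookkeeping: every bead belongs to
one molecule, every molecule has a species label, and lipid species carry
their :class:`~cgbilayer.forcefield.LipidTopology` so that analysis code
can find head beads and tail beads without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .forcefield import ForceFieldError, LipidTopology

__all__ = ["System"]


@dataclass
class System:
    coords: np.ndarray  # (N, 3) A
    velocities: np.ndarray  # (N, 3) A/ps
    types: np.ndarray  # (N,) str
    charges: np.ndarray  # (N,) e
    masses: np.ndarray  # (N,) amu
    mol_index: np.ndarray  # (N,) int, contiguous per molecule
    species: list  # per-molecule species label
    box: np.ndarray  # (3,) A, orthorhombic
    topologies: dict = field(default_factory=dict)  # lipid species -> topology
    leaflet: np.ndarray | None = None  # per-molecule: +1 upper, -1 lower, 0 n/a

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        n = len(self.coords)
        for name in ("velocities", "types", "charges", "masses", "mol_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coords")
        if self.leaflet is None:
            self.leaflet = np.zeros(self.n_molecules, dtype=int)

    # -- sizes ---------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    # -- molecule views ------------------------------------------------------

    def mol_slice(self, mol: int) -> slice:
        """Bead slice of one molecule (bead indices are contiguous per molecule)."""
        start = int(np.searchsorted(self.mol_index, mol, side="left"))
        stop = int(np.searchsorted(self.mol_index, mol, side="right"))
        return slice(start, stop)

    def lipid_mols(self) -> np.ndarray:
        """Molecule ids whose species has a registered lipid topology."""
        return np.array(
            [m for m, sp in enumerate(self.species) if sp in self.topologies],
            dtype=int,
        )

    def lipid_bead_indices(self, which: str = "all") -> np.ndarray:
        """Global bead indices over all lipids.

        which: "all", "head", "c1" (first tail bead of each tail), or
        "tail" (all tail beads).
        """
        out: list[int] = []
        for m in self.lipid_mols():
            topo: LipidTopology = self.topologies[self.species[m]]
            base = self.mol_slice(m).start
            if which == "all":
                out.extend(range(base, base + topo.n_beads))
            elif which == "head":
                out.extend(base + i for i in topo.head_beads)
            elif which == "c1":
                out.extend(base + i for i in topo.c1_indices())
            elif which == "tail":
                for t in topo.tails:
                    out.extend(base + i for i in t.beads)
            else:
                raise ValueError(f"unknown selection {which!r}")
        return np.array(out, dtype=int)

    def bonded_arrays(self):
        """Global bond and angle term arrays across all molecules.

        Returns (bond_ij, bond_r0, bond_k, angle_ijk, angle_theta0, angle_k).
        """
        bij, br0, bk = [], [], []
        aijk, at0, ak = [], [], []
        for m, sp in enumerate(self.species):
            topo = self.topologies.get(sp)
            if topo is None:
                continue
            base = self.mol_slice(m).start
            for b in topo.bonds:
                bij.append((base + b.i, base + b.j))
                br0.append(b.r0)
                bk.append(b.k)
            for a in topo.angles:
                aijk.append((base + a.i, base + a.j, base + a.k_))
                at0.append(a.theta0)
                ak.append(a.k)
        return (
            np.array(bij, dtype=int).reshape(-1, 2),
            np.array(br0, dtype=float),
            np.array(bk, dtype=float),
            np.array(aijk, dtype=int).reshape(-1, 3),
            np.array(at0, dtype=float),
            np.array(ak, dtype=float),
        )

    # -- geometry ------------------------------------------------------------

    def wrap(self) -> None:
        """Wrap coordinates into [0, L) in place."""
        self.coords -= np.floor(self.coords / self.box) * self.box

    def copy(self) -> "System":
        return System(
            coords=self.coords.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            charges=self.charges.copy(),
            masses=self.masses.copy(),
            mol_index=self.mol_index.copy(),
            species=list(self.species),
            box=self.box.copy(),
            topologies=dict(self.topologies),
            leaflet=None if self.leaflet is None else self.leaflet.copy(),
        )

    @property
    def net_charge(self) -> int:
        total = float(self.charges.sum())
        rounded = int(round(total))
        if abs(total - rounded) > 1e-6:
            raise ForceFieldError(f"non-integer total charge {total}")
        return rounded
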