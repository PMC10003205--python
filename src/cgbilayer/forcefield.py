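"""Bead types, lipid topologies and nonbonded interaction tables.

The force field is MARTINI-style: a small alphabet of bead types whose
pairwise Lennard-Jones well depths are drawn from a ladder of discrete
interaction levels on a (mostly) common sigma, harmonic bonds, and
cosine-harmonic angles. Every parameter is read from a structured YAML
config; a bundled default carries standard values for POPC and
placeholder bonded terms for the imidazole (ISUCA) headgroup, flagged
``supplementary_required`` until parameterized values are supplied.

Four lipid species are defined: POPC (12 beads: choline + phosphate head,
two glycerol beads, two 4-bead tails) and three ISUCA-derived lipids
(13 beads: 3-bead imidazole ring, two glycerol beads, two 4-bead tails)
differing in tail saturation. Protonating the imidazole ring switches one
ring bead to a +1 charged type, which is how these lipids respond to low pH.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "BeadSpec",
    "BondTerm",
    "AngleTerm",
    "LipidTopology",
    "ForceFieldTables",
    "ForceFieldError",
    "load_forcefield",
    "lipid_topology",
    "net_charge",
    "default_config_path",
    "LIPID_SPECIES",
]

LIPID_SPECIES = ("POPC", "ISUCA-2 Pal", "ISUCA-2 Ol", "ISUCA-Pal-Ol")


class ForceFieldError(ValueError):
    """Raised for malformed or incomplete force-field input."""


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: ~4 heavy atoms mapped to a single particle."""

    name: str
    bead_type: str
    charge: float
    mass: float

    def __post_init__(self) -> None:
        if abs(self.charge - round(self.charge)) > 1e-9:
            raise ForceFieldError(
                f"bead {self.name}: charge {self.charge} is not an integer "
                "multiple of e"
            )
        if self.mass <= 0:
            raise ForceFieldError(f"bead {self.name}: mass must be positive")


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond V = k/2 (r - r0)^2 between two beads of one molecule."""

    i: int
    j: int
    r0: float  # A
    k: float  # kJ/mol/A^2

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ForceFieldError("bond indices must be distinct")
        if self.k < 0:
            raise ForceFieldError("bond force constant must be >= 0")
        if self.r0 <= 0:
            raise ForceFieldError("bond length must be positive")


@dataclass(frozen=True)
class AngleTerm:
    """Cosine-harmonic angle V = k/2 (cos theta - cos theta0)^2."""

    i: int
    j: int
    k_: int  # third bead index ("k" is taken by the force constant)
    theta0: float  # degrees
    k: float  # kJ/mol

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k_}) != 3:
            raise ForceFieldError("angle indices must be distinct")
        if self.k < 0:
            raise ForceFieldError("angle force constant must be >= 0")
        if not 0.0 < self.theta0 <= 180.0:
            raise ForceFieldError("equilibrium angle must be in (0, 180] deg")


@dataclass(frozen=True)
class Tail:
    kind: str  # "pal" (saturated) or "ol" (unsaturated)
    beads: tuple[int, ...]  # indices of C1..C4, glycerol end first


@dataclass(frozen=True)
class LipidTopology:
    species: str
    beads: tuple[BeadSpec, ...]
    bonds: tuple[BondTerm, ...]
    angles: tuple[AngleTerm, ...]
    head_beads: tuple[int, ...]
    tails: tuple[Tail, ...]
    protonated: bool = False
    supplementary_required: bool = False

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def net_charge(self) -> int:
        return int(round(sum(b.charge for b in self.beads)))

    def c1_indices(self) -> tuple[int, ...]:
        """Index of the first (glycerol-proximal) bead of each tail."""
        return tuple(t.beads[0] for t in self.tails)

    def validate(self) -> None:
        n = self.n_beads
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ForceFieldError(f"{self.species}: bond index out of range")
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k_)):
                raise ForceFieldError(f"{self.species}: angle index out of range")
        for t in self.tails:
            if len(t.beads) != 4:
                raise ForceFieldError(
                    f"{self.species}: each tail must have exactly 4 beads"
                )
            if t.kind not in ("pal", "ol"):
                raise ForceFieldError(f"{self.species}: unknown tail kind {t.kind}")
        if not self._connected():
            raise ForceFieldError(f"{self.species}: bond graph is not connected")

    def _connected(self) -> bool:
        if self.n_beads == 0:
            return False
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_beads)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        seen = {0}
        queue = deque([0])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_beads

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "supplementary_required": self.supplementary_required,
            "beads": [
                {"name": b.name, "type": b.bead_type, "charge": int(round(b.charge))}
                for b in self.beads
            ],
            "bonds": [
                {"indices": [b.i, b.j], "r0": b.r0, "k": b.k} for b in self.bonds
            ],
            "angles": [
                {"indices": [a.i, a.j, a.k_], "theta0": a.theta0, "k": a.k}
                for a in self.angles
            ],
            "head_beads": list(self.head_beads),
            "tails": [{"kind": t.kind, "beads": list(t.beads)} for t in self.tails],
        }

    @classmethod
    def from_dict(
        cls,
        species: str,
        data: Mapping,
        masses: Mapping[str, float],
        protonated: bool = False,
    ) -> "LipidTopology":
        beads = []
        for entry in data["beads"]:
            btype = entry["type"]
            if btype not in masses:
                raise ForceFieldError(
                    f"{species}: undefined bead type {btype!r} in topology"
                )
            beads.append(
                BeadSpec(
                    name=entry["name"],
                    bead_type=btype,
                    charge=float(entry.get("charge", 0)),
                    mass=float(masses[btype]),
                )
            )
        bonds = tuple(
            BondTerm(i=e["indices"][0], j=e["indices"][1], r0=float(e["r0"]),
                     k=float(e["k"]))
            for e in data.get("bonds", ())
        )
        angles = tuple(
            AngleTerm(i=e["indices"][0], j=e["indices"][1], k_=e["indices"][2],
                      theta0=float(e["theta0"]), k=float(e["k"]))
            for e in data.get("angles", ())
        )
        topo = cls(
            species=species,
            beads=tuple(beads),
            bonds=bonds,
            angles=angles,
            head_beads=tuple(data.get("head_beads", ())),
            tails=tuple(
                Tail(kind=t["kind"], beads=tuple(t["beads"]))
                for t in data.get("tails", ())
            ),
            protonated=protonated,
            supplementary_required=bool(data.get("supplementary_required", False)),
        )
        topo.validate()
        return topo


@dataclass(frozen=True)
class SolventSpec:
    name: str
    bead_type: str
    charge: float


@dataclass
class ForceFieldTables:
    """Complete, symmetric nonbonded matrix plus bonded/bookkeeping tables.

    ``pair_table`` maps a frozenset-like sorted type pair to (epsilon, sigma)
    in kJ/mol and A. Lookups on undefined bead types or missing pairs raise;
    there is deliberately no silent default.
    """

    pair_table: dict[tuple[str, str], tuple[float, float]]
    bead_masses: dict[str, float]
    coulomb_constant: float
    relative_dielectric: float
    bonded_defaults: dict
    topologies: dict[str, LipidTopology]
    solvent: dict[str, SolventSpec]
    protonation_rule: dict
    source: str = "<builtin>"

    def lookup(self, type_a: str, type_b: str) -> tuple[float, float]:
        for t in (type_a, type_b):
            if t not in self.bead_masses:
                raise ForceFieldError(f"undefined bead type {t!r}")
        key = (type_a, type_b) if type_a <= type_b else (type_b, type_a)
        try:
            return self.pair_table[key]
        except KeyError:
            raise ForceFieldError(
                f"no nonbonded parameters for pair ({type_a}, {type_b})"
            ) from None

    def mass(self, bead_type: str) -> float:
        try:
            return self.bead_masses[bead_type]
        except KeyError:
            raise ForceFieldError(f"undefined bead type {bead_type!r}") from None

    @property
    def bead_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.bead_masses))


def default_config_path() -> Path:
    """Path of the bundled force-field config."""
    return Path(resources.files("cgbilayer") / "data" / "martini_cg.yaml")


def load_forcefield(config_source: str | Path | None = None) -> ForceFieldTables:
    """Load force-field tables from a YAML config (bundled default if None).

    The nonbonded section is expanded into a complete explicit symmetric
    matrix over every declared bead type: alias types (ring beads,
    antifreeze) inherit the level row of their base type, pairs of two
    S-class ring beads get reduced sigma and scaled epsilon, and explicit
    overrides are applied last. Any contradiction or gap is an error.
    """
    if config_source is None:
        config_source = default_config_path()
    path = Path(config_source)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    masses = {t: float(v["mass"]) for t, v in cfg["bead_types"].items()}
    nb = cfg["nonbonded"]
    levels: Mapping[str, float] = nb["levels"]
    level_sigma: Mapping[str, float] = nb.get("level_sigma", {})
    sigma_default = float(nb["sigma_default"])
    aliases: Mapping[str, str] = nb.get("aliases", {})
    for alias, base in aliases.items():
        if base not in masses and base not in _base_types(nb):
            raise ForceFieldError(f"alias {alias} -> unknown base type {base}")

    base_levels: dict[tuple[str, str], str] = {}
    for entry in nb["pairs"]:
        a, b, lvl = entry
        if lvl not in levels:
            raise ForceFieldError(f"unknown interaction level {lvl!r}")
        key = (a, b) if a <= b else (b, a)
        if key in base_levels and base_levels[key] != lvl:
            raise ForceFieldError(f"asymmetric/conflicting entries for pair {key}")
        base_levels[key] = lvl

    def base_of(t: str) -> str:
        return aliases.get(t, t)

    ring_sigma = float(nb.get("ring_sigma", sigma_default))
    ring_scale = float(nb.get("ring_epsilon_scale", 1.0))

    pair_table: dict[tuple[str, str], tuple[float, float]] = {}
    declared = sorted(masses)
    for i, a in enumerate(declared):
        for b in declared[i:]:
            ba, bb = base_of(a), base_of(b)
            key = (ba, bb) if ba <= bb else (bb, ba)
            if key not in base_levels:
                raise ForceFieldError(
                    f"incomplete matrix: no level for pair ({a}, {b})"
                )
            lvl = base_levels[key]
            eps = float(levels[lvl])
            sigma = float(level_sigma.get(lvl, sigma_default))
            if a.startswith("S") and b.startswith("S"):
                eps *= ring_scale
                sigma = ring_sigma
            if eps <= 0 or sigma <= 0:
                raise ForceFieldError(f"non-positive epsilon/sigma for ({a}, {b})")
            pair_table[(a, b)] = (eps, sigma)

    for ov in nb.get("overrides", ()):
        a, b = ov["types"]
        key = (a, b) if a <= b else (b, a)
        if a not in masses or b not in masses:
            raise ForceFieldError(f"override references undefined type: {ov}")
        eps, sigma = float(ov["epsilon"]), float(ov["sigma"])
        if eps <= 0 or sigma <= 0:
            raise ForceFieldError(f"non-positive epsilon/sigma in override {ov}")
        pair_table[key] = (eps, sigma)

    topologies = {
        sp: LipidTopology.from_dict(sp, data, masses)
        for sp, data in cfg.get("topologies", {}).items()
    }
    solvent = {
        role: SolventSpec(name=v["name"], bead_type=v["type"],
                          charge=float(v.get("charge", 0)))
        for role, v in cfg.get("solvent", {}).items()
    }
    for sv in solvent.values():
        if sv.bead_type not in masses:
            raise ForceFieldError(f"solvent bead type {sv.bead_type!r} undefined")

    elec = cfg["electrostatics"]
    return ForceFieldTables(
        pair_table=pair_table,
        bead_masses=masses,
        coulomb_constant=float(elec["coulomb_constant"]),
        relative_dielectric=float(elec["relative_dielectric"]),
        bonded_defaults=cfg.get("bonded_defaults", {}),
        topologies=topologies,
        solvent=solvent,
        protonation_rule=cfg.get("protonation", {}),
        source=str(path),
    )


def _base_types(nb: Mapping) -> set[str]:
    out: set[str] = set()
    for a, b, _ in nb["pairs"]:
        out.add(a)
        out.add(b)
    return out


_DEFAULT_TABLES: ForceFieldTables | None = None


def default_forcefield() -> ForceFieldTables:
    """Bundled force field, loaded once per process."""
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_forcefield()
    return _DEFAULT_TABLES


def lipid_topology(
    species: str,
    protonated: bool = False,
    tables: ForceFieldTables | None = None,
) -> LipidTopology:
    """Topology for one lipid species, optionally protonated at the imidazole.

    Protonation is only meaningful for the ISUCA-derived species; requesting
    a protonated POPC is an error. The protonation rule (which ring bead
    switches to a charged type) comes from the force-field config.
    """
    tables = tables or default_forcefield()
    if species not in tables.topologies:
        raise ForceFieldError(
            f"unknown species {species!r}; known: {sorted(tables.topologies)}"
        )
    topo = tables.topologies[species]
    if not protonated:
        return topo
    if "ISUCA" not in species:
        raise ForceFieldError(f"protonation is not defined for {species}")
    rule = tables.protonation_rule
    if not rule:
        raise ForceFieldError("force field defines no protonation rule")
    target, new_type, new_charge = (
        rule["bead_name"], rule["new_type"], float(rule["new_charge"]),
    )
    beads = []
    hit = False
    for b in topo.beads:
        if b.name == target:
            beads.append(
                BeadSpec(name=b.name, bead_type=new_type, charge=new_charge,
                         mass=tables.mass(new_type))
            )
            hit = True
        else:
            beads.append(b)
    if not hit:
        raise ForceFieldError(
            f"protonation target bead {target!r} absent from {species}"
        )
    return replace(topo, beads=tuple(beads), protonated=True)


def net_charge(obj) -> int:
    """Total charge (in e) of a topology, a system, or anything with charges.

    Accepts a LipidTopology, a System (anything exposing a ``charges``
    array), or a plain iterable of charges.
    """
    if isinstance(obj, LipidTopology):
        return obj.net_charge
    charges = getattr(obj, "charges", obj)
    total = float(sum(charges))
    rounded = int(round(total))
    if abs(total - rounded) > 1e-6:
        raise ForceFieldError(f"non-integer total charge {total}")
    return rounded
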