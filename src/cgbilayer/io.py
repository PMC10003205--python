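"""Readers, writers and run-directory conventions.

A run directory holds:

* ``system.json``  — full system description (authoritative; coordinates,
  types, charges, molecule bookkeeping, topologies)
* ``system.gro`` / ``system.pdb`` — coordinates for visualization
* ``<name>.dcd`` + ``<name>.times.tsv`` — trajectory frames plus a
  plain-text sidecar with per-frame times (actual ns) and box lengths and
  the effective-time factor
* ``metrics.json`` / ``metrics_*.csv`` — analysis output
* ``provenance.json`` — config echo, seed and package version

Binary coordinate formats go through MDAnalysis; everything else is plain
text authored here.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import MetricsReport
from .forcefield import ForceFieldTables, LipidTopology, default_forcefield
from .system import System
from .trajectory import Trajectory

__all__ = [
    "save_system", "load_system", "write_gro", "write_pdb",
    "write_trajectory", "read_trajectory", "write_metrics", "read_metrics",
    "write_provenance", "plot_msd", "plot_p2", "collect_report",
]

# short residue names for the fixed-width coordinate formats
_RESNAMES = {
    "POPC": "POPC",
    "ISUCA-2 Pal": "IS2P",
    "ISUCA-2 Ol": "IS2O",
    "ISUCA-Pal-Ol": "ISPO",
    "ISUCA-2 Pal+": "IS2H",
    "ISUCA-2 Ol+": "ISOH",
    "ISUCA-Pal-Ol+": "ISPH",
    "W": "W", "WF": "WF", "CL": "CL",
}


def _mda_universe(system: System):
    import MDAnalysis as mda

    n = system.n_beads
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=system.n_molecules,
        atom_resindex=system.mol_index,
        trajectory=True,
    )
    names = []
    for m, sp in enumerate(system.species):
        topo = system.topologies.get(sp)
        if topo is not None:
            names.extend(b.name for b in topo.beads)
        else:
            sl = system.mol_slice(m)
            names.extend([sp] * (sl.stop - sl.start))
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr(
        "resnames",
        [_RESNAMES.get(sp, sp[:4] or "MOL") for sp in system.species],
    )
    u.add_TopologyAttr("resids", np.arange(1, system.n_molecules + 1))
    u.atoms.positions = system.coords.astype(np.float32)
    u.dimensions = [*system.box, 90.0, 90.0, 90.0]
    return u


def write_gro(system: System, path: str | Path) -> None:
    _mda_universe(system).atoms.write(str(path))


def write_pdb(system: System, path: str | Path) -> None:
    _mda_universe(system).atoms.write(str(path))


def save_system(system: System, run_dir: str | Path) -> Path:
    """Write system.json (+ GRO and PDB snapshots) into a run directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "coords": system.coords.tolist(),
        "velocities": system.velocities.tolist(),
        "types": list(system.types),
        "charges": system.charges.tolist(),
        "masses": system.masses.tolist(),
        "mol_index": system.mol_index.tolist(),
        "species": list(system.species),
        "box": system.box.tolist(),
        "leaflet": system.leaflet.tolist(),
        "topologies": {sp: t.to_dict() for sp, t in system.topologies.items()},
        "topology_protonated": {
            sp: t.protonated for sp, t in system.topologies.items()
        },
    }
    path = run_dir / "system.json"
    path.write_text(json.dumps(payload))
    write_gro(system, run_dir / "system.gro")
    write_pdb(system, run_dir / "system.pdb")
    return path


def load_system(run_dir: str | Path,
                tables: ForceFieldTables | None = None) -> System:
    run_dir = Path(run_dir)
    path = run_dir / "system.json" if run_dir.is_dir() else run_dir
    if not path.exists():
        raise FileNotFoundError(f"no system.json under {run_dir}")
    tables = tables or default_forcefield()
    data = json.loads(path.read_text())
    topologies = {
        sp: LipidTopology.from_dict(
            sp.rstrip("+"), tdata, tables.bead_masses,
            protonated=data.get("topology_protonated", {}).get(sp, False),
        )
        for sp, tdata in data["topologies"].items()
    }
    # from_dict uses the bare species name; restore the labelled key
    topologies = {sp: t for sp, t in topologies.items()}
    return System(
        coords=np.array(data["coords"], float),
        velocities=np.array(data["velocities"], float),
        types=np.array(data["types"], dtype=object),
        charges=np.array(data["charges"], float),
        masses=np.array(data["masses"], float),
        mol_index=np.array(data["mol_index"], int),
        species=list(data["species"]),
        box=np.array(data["box"], float),
        topologies=topologies,
        leaflet=np.array(data["leaflet"], int),
    )


# ---------------------------------------------------------------------------
# trajectories: DCD + plain-text time/box sidecar


def write_trajectory(traj: Trajectory, system: System, run_dir: str | Path,
                     name: str = "traj") -> Path:
    import MDAnalysis as mda

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    u = _mda_universe(system)
    dcd = run_dir / f"{name}.dcd"
    with mda.Writer(str(dcd), n_atoms=traj.n_beads) as writer:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f].astype(np.float32)
            u.dimensions = [*traj.boxes[f], 90.0, 90.0, 90.0]
            writer.write(u.atoms)
    sidecar = run_dir / f"{name}.times.tsv"
    with open(sidecar, "w") as fh:
        fh.write(f"# effective_time_factor\t{traj.effective_time_factor}\n")
        fh.write(f"# wrapped\t{int(traj.wrapped)}\n")
        fh.write("frame\ttime_ns\tbox_x\tbox_y\tbox_z\n")
        for f in range(traj.n_frames):
            fh.write(
                f"{f}\t{traj.times[f]:.9g}\t{traj.boxes[f, 0]:.9g}"
                f"\t{traj.boxes[f, 1]:.9g}\t{traj.boxes[f, 2]:.9g}\n"
            )
    return dcd


def read_trajectory(run_dir: str | Path, name: str = "traj") -> Trajectory:
    import MDAnalysis as mda

    run_dir = Path(run_dir)
    dcd = run_dir / f"{name}.dcd"
    sidecar = run_dir / f"{name}.times.tsv"
    if not dcd.exists():
        raise FileNotFoundError(f"no trajectory found under {run_dir}")
    factor, wrapped = 1.0, True
    with open(sidecar) as fh:
        header = []
        for line in fh:
            if line.startswith("# effective_time_factor"):
                factor = float(line.split("\t")[1])
            elif line.startswith("# wrapped"):
                wrapped = bool(int(line.split("\t")[1]))
            elif not line.startswith("#"):
                header.append(line)
                break
        table = pd.read_csv(fh, sep="\t", names=header[0].split())
    times = table["time_ns"].to_numpy(float)
    boxes = table[["box_x", "box_y", "box_z"]].to_numpy(float)
    u = mda.Universe.empty(n_atoms=0, trajectory=True)
    reader = mda.coordinates.DCD.DCDReader(str(dcd))
    coords = np.array([ts.positions.copy() for ts in reader], dtype=float)
    reader.close()
    if len(coords) != len(times):
        raise ValueError("sidecar and DCD frame counts differ")
    return Trajectory(coords=coords, boxes=boxes, times=times,
                      effective_time_factor=factor, wrapped=wrapped)


# ---------------------------------------------------------------------------
# metrics, provenance, plots


def write_metrics(report: MetricsReport, run_dir: str | Path) -> Path:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    path = run_dir / "metrics.json"
    path.write_text(json.dumps(report.to_dict(), indent=2))
    report.p2b.to_csv(run_dir / "metrics_p2_bond.csv", index=False)
    report.p2t.to_csv(run_dir / "metrics_p2_tail.csv", index=False)
    summary = pd.DataFrame([{
        "apl_A2": report.apl.mean, "apl_sd": report.apl.sd,
        "thickness_A": report.thickness.mean,
        "thickness_sd": report.thickness.sd,
        "D_cm2_s": report.diffusion.d_cm2_s,
        "D_stderr": report.diffusion.stderr_cm2_s,
    }])
    summary.to_csv(run_dir / "metrics_summary.csv", index=False)
    return path


def read_metrics(run_dir: str | Path) -> dict:
    path = Path(run_dir) / "metrics.json"
    if not path.exists():
        raise FileNotFoundError(f"no metrics.json under {run_dir}")
    return json.loads(path.read_text())


def write_provenance(run_dir: str | Path, stage: str, config: dict,
                     seed: int | None = None) -> Path:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    path = run_dir / "provenance.json"
    existing = json.loads(path.read_text()) if path.exists() else {"stages": []}
    existing["version"] = __version__
    existing["stages"].append(
        {"stage": stage, "seed": seed, "config": _jsonable(config)})
    path.write_text(json.dumps(existing, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def plot_msd(lags_ns: np.ndarray, msd: np.ndarray, fit, path: str | Path,
             effective_time_factor: float = 1.0) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = np.asarray(lags_ns) * effective_time_factor
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(t, msd, lw=1.5, label="MSD")
    if fit is not None:
        ax.plot(t, 4 * (fit.d_cm2_s / 1e-7) * t, "--",
                label=f"4Dt, D={fit.d_cm2_s:.2e} cm$^2$/s")
    ax.set_xlabel("effective lag time (ns)")
    ax.set_ylabel(r"MSD ($\mathrm{\AA}^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_p2(p2b: pd.DataFrame, p2t: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for (sp, chain), grp in p2b.groupby(["species", "chain"]):
        axes[0].plot(grp["bond"], grp["p2"], "o-", label=f"{sp} ({chain})")
    axes[0].set_ylabel(r"$P_{2b}$")
    axes[0].legend(frameon=False, fontsize=7)
    labels = [f"{r.species}\n({r.chain})" for r in p2t.itertuples()]
    axes[1].bar(range(len(p2t)), p2t["p2"].to_numpy())
    axes[1].set_xticks(range(len(p2t)), labels, fontsize=7)
    axes[1].set_ylabel(r"$P_{2t}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def collect_report(run_dirs, out_dir: str | Path):
    """Assemble structure- and diffusion-table CSVs from analyzed runs.

    Returns (structure_df, diffusion_df); rows are labelled by the run
    directory name unless provenance records a system name.
    """
    rows_s, rows_d = [], []
    for rd in run_dirs:
        rd = Path(rd)
        m = read_metrics(rd)
        label = rd.name
        prov = rd / "provenance.json"
        if prov.exists():
            for st in json.loads(prov.read_text()).get("stages", []):
                name = (st.get("config") or {}).get("system")
                if name:
                    label = name
        rows_s.append({
            "model": label,
            "APL_A2": m["apl_A2"]["mean"], "APL_sd": m["apl_A2"]["sd"],
            "thickness_A": m["hydrophobic_thickness_A"]["mean"],
            "thickness_sd": m["hydrophobic_thickness_A"]["sd"],
        })
        rows_d.append({
            "model": label,
            "D_1e7_cm2_s": m["diffusion"]["D_cm2_s"] / 1e-7,
        })
    df_s, df_d = pd.DataFrame(rows_s), pd.DataFrame(rows_d)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df_s.to_csv(out_dir / "structure_table.csv", index=False)
    df_d.to_csv(out_dir / "diffusion_table.csv", index=False)
    return df_s, df_d
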