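"""File I/O: FASTA sequences, coarse-grained coordinate files, tidy CSVs.

Single frames are read from PDB or GRO files and trajectories from
multi-model PDB files (all via MDAnalysis), with bead radii and molecule
tags assigned from residue names through a user-editable mapping table.
Positions are converted to nm internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .apr import APRSet
from .sasa import DEFAULT_BEAD_RADIUS, BeadFrame, BeadTrajectory, SASASeries

#: resname -> (molecule_tag, radius_nm) defaults used when no mapping file is given.
DEFAULT_RESNAME_MAP: dict[str, tuple[str, float]] = {
    "PRT": ("protein", DEFAULT_BEAD_RADIUS),
    "EXC": ("excipient", DEFAULT_BEAD_RADIUS),
    "W": ("solvent", DEFAULT_BEAD_RADIUS),
    "PW": ("solvent", DEFAULT_BEAD_RADIUS),
    "ION": ("ion", DEFAULT_BEAD_RADIUS),
    "NA": ("ion", DEFAULT_BEAD_RADIUS),
    "CL": ("ion", DEFAULT_BEAD_RADIUS),
}


def read_fasta(path: str | Path, record_id: str | None = None) -> str:
    """Sequence of the first (or the named) record of a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        return str(records[0].seq).upper()
    for record in records:
        if record.id == record_id:
            return str(record.seq).upper()
    raise KeyError(f"record {record_id!r} not found in {path}")


def load_resname_map(path: str | Path | None) -> dict[str, tuple[str, float]]:
    """Load a resname -> (tag, radius) TSV: columns resname, tag, radius_nm."""
    if path is None:
        return dict(DEFAULT_RESNAME_MAP)
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"resname", "tag", "radius_nm"}
    if not required.issubset(table.columns):
        raise ValueError(f"mapping file must have columns {sorted(required)}")
    return {
        str(row.resname): (str(row.tag), float(row.radius_nm))
        for row in table.itertuples()
    }


def _frame_from_atomgroup(universe, resname_map: dict) -> BeadFrame:
    atoms = universe.atoms
    resnames = atoms.resnames
    tags, radii = [], []
    for resname in resnames:
        if resname not in resname_map:
            raise KeyError(
                f"residue name {resname!r} not in mapping table; add it to the radii/tag TSV"
            )
        tag, radius = resname_map[resname]
        tags.append(tag)
        radii.append(radius)
    box_edge = None
    if universe.dimensions is not None and universe.dimensions[0] > 0:
        box_edge = float(universe.dimensions[0]) / 10.0
    return BeadFrame(
        coordinates=atoms.positions.astype(float) / 10.0,  # A -> nm
        radii=np.array(radii),
        residue_index=atoms.resids.astype(int),
        molecule_tag=np.array(tags),
        molecule_id=atoms.molnums.astype(int) if hasattr(atoms, "molnums") else None,
        box_edge=box_edge,
    )


def read_frame(path: str | Path, resname_map_path: str | Path | None = None) -> BeadFrame:
    """Read a single-frame PDB or GRO coordinate file."""
    import MDAnalysis as mda

    resname_map = load_resname_map(resname_map_path)
    universe = mda.Universe(str(path))
    return _frame_from_atomgroup(universe, resname_map)


def read_trajectory(
    path: str | Path,
    topology: str | Path | None = None,
    resname_map_path: str | Path | None = None,
    dt_ps: float = 1000.0,
) -> BeadTrajectory:
    """Read a multi-frame trajectory (multi-model PDB, or any MDAnalysis-
    readable trajectory paired with a topology frame)."""
    import MDAnalysis as mda

    resname_map = load_resname_map(resname_map_path)
    if topology is None:
        universe = mda.Universe(str(path))
    else:
        universe = mda.Universe(str(topology), str(path))
    frames = []
    times = []
    for ts in universe.trajectory:
        frames.append(_frame_from_atomgroup(universe, resname_map))
        times.append(ts.time if ts.time is not None else len(times) * dt_ps)
    return BeadTrajectory(frames=tuple(frames), frame_times=np.array(times, dtype=float))


def write_trajectory_pdb(traj: BeadTrajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (coordinates nm -> A).

    Molecule tags are encoded as residue names (protein -> PRT, excipient ->
    EXC, solvent -> W, ion -> ION) so round-tripping through
    :func:`read_trajectory` with the default mapping restores them.
    """
    tag_to_resname = {"protein": "PRT", "excipient": "EXC", "solvent": "W", "ion": "ION"}
    first = traj.frames[0]
    with open(path, "w") as fh:
        for model, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {model:4d}\n")
            if frame.box_edge is not None:
                edge = frame.box_edge * 10.0
                fh.write(
                    f"CRYST1{edge:9.3f}{edge:9.3f}{edge:9.3f}"
                    "  90.00  90.00  90.00 P 1           1\n"
                )
            for i in range(frame.n_beads):
                x, y, z = frame.coordinates[i] * 10.0
                resname = tag_to_resname[str(frame.molecule_tag[i])]
                resid = int(frame.residue_index[i]) % 10000
                serial = (i + 1) % 100000
                fh.write(
                    f"ATOM  {serial:5d}  BB  {resname:<4s}{'A'}{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_sasa_csv(series_list: list[SASASeries], path: str | Path) -> None:
    """Write SASA series as tidy CSV (system, replicate, frame, time_ps, total, apr)."""
    rows = []
    for series in series_list:
        for k in range(series.per_frame_total.size):
            rows.append(
                {
                    "system": series.system_id,
                    "replicate": series.replicate_id,
                    "frame": k,
                    "time_ps": series.frame_times[k],
                    "total_sasa_nm2": series.per_frame_total[k],
                    "apr_sasa_nm2": series.per_frame_apr[k],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sasa_csv(path: str | Path) -> list[SASASeries]:
    """Read back SASA series from the tidy CSV written by :func:`write_sasa_csv`."""
    table = pd.read_csv(path)
    series = []
    for (system, replicate), sub in table.groupby(["system", "replicate"], dropna=False):
        sub = sub.sort_values("frame")
        series.append(
            SASASeries(
                per_frame_total=sub["total_sasa_nm2"].to_numpy(),
                per_frame_apr=sub["apr_sasa_nm2"].to_numpy(),
                frame_times=sub["time_ps"].to_numpy(),
                system_id=str(system),
                replicate_id=str(replicate),
            )
        )
    return series


def write_aprs_json(aprs: APRSet, path: str | Path, extra: dict | None = None) -> None:
    payload = aprs.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_aprs_json(path: str | Path) -> APRSet:
    payload = json.loads(Path(path).read_text())
    return APRSet(
        patches=tuple(tuple(p) for p in payload["patches"]),
        sequence_length=payload["sequence_length"],
        parameters=payload.get("parameters", {}),
    )


def default_hsa_sequence() -> str:
    """The bundled mature HSA sequence (585 residues)."""
    from importlib import resources

    with resources.as_file(
        resources.files("aprshield.data").joinpath("hsa_mature.fasta")
    ) as p:
        return read_fasta(p)
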