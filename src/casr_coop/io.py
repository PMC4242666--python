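"""Readers and writers for the pipeline's plain-text formats.

Fixed conventions: concentrations in mM, times in seconds, coordinates in
Angstrom. Traces are long-format CSV (``cell_id,time_s,ratio``), protocols
JSON or CSV, dose-response tables CSV, correlation matrices CSV with a
residue-label header, and ensembles either multi-model PDB (MODEL/ENDMDL
records, one CA atom per residue) or plain whitespace XYZ blocks separated
by blank lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import TrajectoryEnsemble
from .oscillation import Trace
from .protocol import StepProtocol

__all__ = [
    "write_traces",
    "read_traces",
    "write_ensemble_pdb",
    "read_ensemble_pdb",
    "write_ensemble_xyz",
    "read_ensemble_xyz",
    "read_sites_json",
]


def write_traces(traces: Sequence[Trace], path: str | Path) -> None:
    """Write traces as long-format CSV ``cell_id,time_s,ratio``."""
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(
        path, index=False
    )


def read_traces(path: str | Path, protocol_path: str | Path) -> list[Trace]:
    """Read traces and bind them to a protocol.

    Malformed rows are rejected with their 1-based file line numbers (the
    header is line 1). Each cell's time grid must be uniform.
    """
    protocol = (
        StepProtocol.from_json(protocol_path)
        if str(protocol_path).endswith(".json")
        else StepProtocol.from_csv(protocol_path)
    )
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = {"cell_id", "time_s", "ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    for col in ("time_s", "ratio"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(f"non-numeric {col!r} on line(s) {lines}")
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise ValueError(f"missing {col!r} on line {line}")
        df[col] = values
    traces = []
    for cid, group in df.groupby("cell_id", sort=False):
        traces.append(
            Trace(
                cell_id=str(cid),
                times_s=group["time_s"].to_numpy(),
                ratios=group["ratio"].to_numpy(),
                protocol=protocol,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# ensembles


def write_ensemble_pdb(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Write a multi-model PDB with one CA atom per residue."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ens.n_residues
    template = struc.AtomArray(n)
    template.coord = ens.coords[0]
    template.chain_id = np.full(n, "A")
    template.res_id = np.arange(1, n + 1)
    template.res_name = np.full(n, "ALA")
    template.atom_name = np.full(n, "CA")
    template.element = np.full(n, "C")
    stack = struc.AtomArrayStack(ens.n_frames, n)
    for annot in template.get_annotation_categories():
        stack.set_annotation(annot, template.get_annotation(annot))
    stack.coord = ens.coords.copy()
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))


def read_ensemble_pdb(path: str | Path) -> TrajectoryEnsemble:
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"]
    labels = [f"R{i}" for i in ca.res_id[0 : ca.array_length()]]
    return TrajectoryEnsemble(coords=np.asarray(ca.coord, float), labels=labels)


def write_ensemble_xyz(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Plain whitespace XYZ: one ``x y z`` line per residue, frames
    separated by blank lines."""
    with open(path, "w") as fh:
        for frame in ens.coords:
            for x, y, z in frame:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            fh.write("\n")


def read_ensemble_xyz(path: str | Path) -> TrajectoryEnsemble:
    frames, current = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            if current:
                frames.append(current)
                current = []
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"XYZ line must have 3 fields, got: {raw!r}")
        current.append([float(p) for p in parts])
    if current:
        frames.append(current)
    if not frames:
        raise ValueError("no frames in XYZ file")
    coords = np.asarray(frames, dtype=float)
    if coords.ndim != 3:
        raise ValueError("frames have inconsistent residue counts")
    return TrajectoryEnsemble(coords=coords)


def read_sites_json(path: str | Path) -> dict[str, list[int]]:
    """Named residue-index sets (e.g. calcium-binding sites) from JSON."""
    payload = json.loads(Path(path).read_text())
    return {str(k): [int(i) for i in v] for k, v in payload.items()}
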