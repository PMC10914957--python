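"""Readers and writers: multi-model PDB, GRO, result tables, exchange logs.

Structure parsing is delegated to biotite; this module adds unit conversion
(file Angstrom <-> internal nm for PDB; biotite already normalises GRO),
topology construction from the chemical tables, and the validation the
pipeline relies on (orthorhombic box present, identical atom order across
models).

The replica-exchange log dialect is defined by this package (see README):
whitespace-delimited lines ``time_ps  i  j  accepted`` where ``(i, j)`` is
an adjacent pair of temperature-rung indices and ``accepted`` is 0 or 1.
Lines starting with ``#`` are comments; an optional header comment
``# n_replicas N`` fixes the ladder size explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem
from .core import (
    AtomRecord,
    FileFormatError,
    Frame,
    RegionMap,
    StructuredSystem,
    TrajectoryEnsemble,
    build_system,
)

_A_PER_NM = 10.0


def _atom_mass(residue_name: str, atom_name: str, element: str) -> float:
    """Mass lookup mirroring the generator conventions: the CB pseudo side
    chain carries the whole side-chain mass, everything else is elemental."""
    resname = residue_name.upper()
    if resname in chem.PEPTIDE_RESNAMES and atom_name == "CB":
        return chem.SIDECHAIN_MASS[resname]
    try:
        return chem.ELEMENT_MASS[element]
    except KeyError:
        raise FileFormatError(
            f"no mass for element {element!r} (atom {atom_name} in {resname})"
        ) from None


def _element_of(atom_name: str, element_hint: str | None) -> str:
    if element_hint:
        el = element_hint.strip().capitalize()
        if el in chem.ELEMENT_MASS:
            return el
    return chem.element_from_name(atom_name)


def _records_from_atom_array(arr) -> list[AtomRecord]:
    records = []
    elements = (
        arr.element if "element" in arr.get_annotation_categories() else None
    )
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        hint = str(elements[i]) if elements is not None else None
        element = _element_of(name, hint)
        resname = str(arr.res_name[i]).upper()
        records.append(
            AtomRecord(
                serial=i + 1,
                name=name,
                element=element,
                mass=_atom_mass(resname, name, element),
                residue_index=int(arr.res_id[i]),
                residue_name=resname,
            )
        )
    return records


def _check_orthorhombic(box_matrix: np.ndarray, path) -> np.ndarray:
    box = np.asarray(box_matrix, dtype=float)
    off = box - np.diag(np.diag(box))
    if not np.allclose(off, 0.0, atol=1e-6):
        raise FileFormatError(
            f"{path}: triclinic box detected; only orthorhombic boxes are "
            "supported"
        )
    edges = np.diag(box)
    if np.any(edges <= 0):
        raise FileFormatError(f"{path}: non-positive box edge length")
    return edges


def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-char elements start at column 14 when the
    # name is short enough
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _pdb_atom_line(serial, name, resname, chain, resid, xyz, element) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(name, element)}"
        f"{'':1s}{resname:<4s}{chain:1s}{resid:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb_multimodel(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB (nm -> Angstrom).

    The writer is internal because the reduced lipid topology uses 4-column
    residue names (POPC/POPS/CHOL/TIP3), which column-strict PDB libraries
    refuse to emit; names occupy columns 18-21.
    """
    system = traj.topology
    box0 = np.asarray(traj.frames[0].box)
    for frame in traj.frames:
        if not np.allclose(frame.box, box0):
            raise FileFormatError(
                "multi-model PDB writing requires a constant box"
            )
    box = box0 * _A_PER_NM
    lines: list[str] = [
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    ]
    for m, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL {m:>8d}")
        coords = frame.coordinates * _A_PER_NM
        for i in range(system.n_atoms):
            chain = "A" if system.group[i] == "peptide" else "B"
            lines.append(
                _pdb_atom_line(
                    int(system.serial[i]) % 100000,
                    str(system.name[i]),
                    str(system.residue_name[i]),
                    chain,
                    int(system.residue_index[i]) % 10000,
                    coords[i],
                    str(system.element[i]),
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb_multimodel(
    path: str | Path,
    region_map: RegionMap | None = None,
    frame_spacing: float = 1.0,
    label: str | None = None,
) -> TrajectoryEnsemble:
    """Read a MODEL/ENDMDL-delimited PDB into an ensemble.

    Coordinates are converted Angstrom -> nm; a CRYST1 record is required
    (periodic analysis needs a box) and must be orthorhombic (90-degree
    angles).  Atom name/residue order must be identical across models.
    Frame times are synthesised as ``i * frame_spacing`` ns because PDB has
    no time field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    box_nm: np.ndarray | None = None
    models: list[list[tuple[str, str, int, float, float, float, str]]] = []
    current: list | None = None
    saw_model_record = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                a, b, c = (
                    float(line[6:15]), float(line[15:24]), float(line[24:33])
                )
                angles = (
                    float(line[33:40]), float(line[40:47]), float(line[47:54])
                )
            except ValueError:
                raise FileFormatError(
                    f"{path}:{lineno}: malformed CRYST1 record"
                ) from None
            if any(abs(ang - 90.0) > 1e-3 for ang in angles):
                raise FileFormatError(
                    f"{path}: triclinic box (angles {angles}); only "
                    "orthorhombic boxes are supported"
                )
            box_nm = np.array([a, b, c]) / _A_PER_NM
        elif rec == "MODEL":
            saw_model_record = True
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise FileFormatError(
                    f"{path}:{lineno}: ENDMDL without matching MODEL"
                )
            models.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model_record:
                    raise FileFormatError(
                        f"{path}:{lineno}: atom record outside MODEL block"
                    )
                current = []
                models.append(current)
                saw_model_record = True
            try:
                current.append(
                    (
                        line[12:16].strip(),
                        line[17:21].strip(),
                        int(line[22:26]),
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                        line[76:78].strip(),
                    )
                )
            except ValueError:
                raise FileFormatError(
                    f"{path}:{lineno}: malformed atom record"
                ) from None
    if not models or not models[0]:
        raise FileFormatError(f"{path}: no atom records found")
    if box_nm is None:
        raise FileFormatError(
            f"{path}: missing CRYST1 record; a periodic box is required"
        )
    ref = models[0]
    for m, model in enumerate(models[1:], start=2):
        if len(model) != len(ref):
            raise FileFormatError(
                f"{path}: atom count mismatch in model {m} "
                f"({len(model)} atoms vs {len(ref)} in model 1)"
            )
        for k, (atom, ref_atom) in enumerate(zip(model, ref)):
            if atom[:3] != ref_atom[:3]:
                raise FileFormatError(
                    f"{path}: atom order mismatch in model {m} at atom "
                    f"{k + 1} ({atom[:3]} vs {ref_atom[:3]})"
                )

    records = []
    for i, (name, resname, resid, _, _, _, element_hint) in enumerate(ref):
        element = _element_of(name, element_hint)
        resname = resname.upper()
        records.append(
            AtomRecord(
                serial=i + 1,
                name=name,
                element=element,
                mass=_atom_mass(resname, name, element),
                residue_index=resid,
                residue_name=resname,
            )
        )
    system = build_system(records, region_map)
    frames = []
    for m, model in enumerate(models):
        coords = np.array(
            [[x, y, z] for (_, _, _, x, y, z, _) in model], dtype=float
        ) / _A_PER_NM
        frames.append(
            Frame(coordinates=coords, box=box_nm.copy(), time=m * frame_spacing)
        )
    return TrajectoryEnsemble(
        topology=system, frames=frames, label=label or path.stem
    )


def _atom_array_from(system: StructuredSystem, frame: Frame):
    import biotite.structure as struc

    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame.coordinates, dtype=np.float32) * _A_PER_NM
    arr.chain_id = np.where(system.group == "peptide", "A", "B")
    arr.res_id = system.residue_index.astype(int)
    arr.res_name = system.residue_name.astype("U5")
    arr.atom_name = system.name.astype("U6")
    arr.element = system.element.astype("U2")
    arr.hetero = system.group != "peptide"
    arr.box = np.diag(np.asarray(frame.box, dtype=float) * _A_PER_NM)
    return arr


def read_gro(
    path: str | Path, region_map: RegionMap | None = None
) -> tuple[StructuredSystem, Frame]:
    """Read a single-frame GRO file -> (system, frame) in nm."""
    from biotite.structure.io.gro import GROFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        gro = GROFile.read(str(path))
        arr = gro.get_structure(model=1)
    except Exception as exc:
        raise FileFormatError(f"{path}: cannot parse GRO ({exc})") from exc
    if arr.box is None:
        raise FileFormatError(f"{path}: missing or malformed GRO box line")
    edges_nm = _check_orthorhombic(arr.box, path) / _A_PER_NM
    records = _records_from_atom_array(arr)
    system = build_system(records, region_map)
    frame = Frame(
        coordinates=np.asarray(arr.coord, dtype=float) / _A_PER_NM,
        box=edges_nm,
    )
    return system, frame


def write_gro(system: StructuredSystem, frame: Frame, path: str | Path) -> None:
    from biotite.structure.io.gro import GROFile

    arr = _atom_array_from(system, frame)
    gro = GROFile()
    gro.set_structure(arr)
    gro.write(str(path))


@dataclass
class ExchangeLog:
    """Replica-exchange attempt record plus the replayed rung occupancy.

    ``replica_temperature_series`` has shape (n_replicas, n_attempts + 1):
    column 0 is the identity start state, column k the state after attempt
    k (in file order).
    """

    n_replicas: int
    attempts: list[tuple[float, tuple[int, int], bool]] = field(
        default_factory=list
    )
    replica_temperature_series: np.ndarray | None = None

    def __post_init__(self):
        if self.n_replicas < 2:
            raise FileFormatError("an exchange log needs >= 2 replicas")
        for time, (i, j), _ in self.attempts:
            if j != i + 1:
                raise FileFormatError(
                    f"non-adjacent exchange pair ({i}, {j}) at t={time} ps"
                )
            if not 0 <= i < self.n_replicas - 1:
                raise FileFormatError(
                    f"rung index {i} outside ladder of {self.n_replicas}"
                )
        if self.replica_temperature_series is None:
            self.replica_temperature_series = replay_exchanges(
                self.n_replicas, self.attempts
            )


def replay_exchanges(
    n_replicas: int, attempts: Sequence[tuple[float, tuple[int, int], bool]]
) -> np.ndarray:
    """Replay accepted swaps from the identity permutation.

    Returns the per-replica rung-index series, shape
    (n_replicas, n_attempts + 1).
    """
    rung_of_replica = np.arange(n_replicas)
    replica_at_rung = np.arange(n_replicas)
    series = np.empty((n_replicas, len(attempts) + 1), dtype=int)
    series[:, 0] = rung_of_replica
    for k, (_, (i, j), accepted) in enumerate(attempts):
        if accepted:
            ra, rb = replica_at_rung[i], replica_at_rung[j]
            replica_at_rung[i], replica_at_rung[j] = rb, ra
            rung_of_replica[ra], rung_of_replica[rb] = j, i
        series[:, k + 1] = rung_of_replica
    return series


def read_exchange_log(path: str | Path) -> ExchangeLog:
    path = Path(path)
    attempts: list[tuple[float, tuple[int, int], bool]] = []
    n_replicas = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"n_replicas\s+(\d+)", line)
                if m:
                    n_replicas = int(m.group(1))
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FileFormatError(
                    f"{path}:{lineno}: expected 'time i j accepted', "
                    f"got {line!r}"
                )
            time, i, j, acc = (
                float(parts[0]), int(parts[1]), int(parts[2]), parts[3]
            )
            if j != i + 1:
                raise FileFormatError(
                    f"{path}:{lineno}: non-adjacent pair ({i}, {j})"
                )
            if acc not in ("0", "1"):
                raise FileFormatError(
                    f"{path}:{lineno}: accepted flag must be 0 or 1"
                )
            attempts.append((time, (i, j), acc == "1"))
    if n_replicas is None:
        if not attempts:
            raise FileFormatError(
                f"{path}: empty log without an '# n_replicas N' header"
            )
        n_replicas = max(j for _, (_, j), _ in attempts) + 1
    return ExchangeLog(n_replicas=n_replicas, attempts=attempts)


def write_exchange_log(log: ExchangeLog, path: str | Path) -> None:
    lines = [f"# n_replicas {log.n_replicas}", "# time_ps i j accepted"]
    for time, (i, j), accepted in log.attempts:
        lines.append(f"{time:g} {i} {j} {1 if accepted else 0}")
    Path(path).write_text("\n".join(lines) + "\n")


def _format_value(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        if np.isinf(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_table(
    records,
    path: str | Path,
    format: str = "tsv",
    comment: str | None = None,
) -> None:
    """Write homogeneous records deterministically.

    ``records`` is a list of dicts sharing a schema or a DataFrame.  Column
    order follows the first record (or the DataFrame); floats are rendered
    at 6 significant digits; NaN/inf become ``NA``.  Identical inputs yield
    byte-identical files.
    """
    if isinstance(records, pd.DataFrame):
        columns = list(records.columns)
        rows = records.to_dict(orient="records")
    else:
        rows = list(records)
        columns = list(rows[0].keys()) if rows else []
        for r in rows:
            if list(r.keys()) != columns:
                raise FileFormatError(
                    "records do not share a common column schema"
                )

    path = Path(path)
    if format == "tsv":
        lines = []
        if comment:
            lines.append(f"# {comment}")
        lines.append("\t".join(columns))
        for r in rows:
            lines.append("\t".join(_format_value(r[c]) for c in columns))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        import json

        def jsonable(v):
            s = _format_value(v)
            if isinstance(v, (bool, np.bool_)):
                return bool(v)
            if isinstance(v, (int, np.integer)):
                return int(v)
            if isinstance(v, (float, np.floating)):
                return None if s == "NA" else float(s)
            return s

        payload = [
            {c: jsonable(r[c]) for c in columns} for r in rows
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise FileFormatError(f"unknown table format {format!r}")
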