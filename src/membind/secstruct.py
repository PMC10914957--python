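"""DSSP-style secondary-structure assignment into seven classes.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
energy (bond if E < -0.5 kcal/mol, amide H reconstructed geometrically when
absent) and translated into patterns:

* two consecutive n->n+4 turns  -> H (alpha helix)
* two consecutive n->n+3 turns  -> G (3-10 helix)
* two consecutive n->n+5 turns  -> I (pi helix)
* bridge ladders                -> E, isolated bridges -> B
* hydrogen-bonded turns         -> T
* otherwise                     -> C

Per-residue priority: H > E > B > G > I > T > C.  Chain termini default to
C unless they sit in a ladder.  Assignments are rigid-motion invariant (the
criterion uses internal distances only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Frame, MembindError, StructuredSystem, TrajectoryEnsemble

SS_CLASSES = ("E", "B", "H", "G", "I", "T", "C")
SS_GROUPS = {
    "unstructured": ("C", "T", "B"),
    "beta": ("E",),
    "helix": ("G", "H", "I"),
}

_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol * Angstrom, Kabsch-Sander prefactor
_EBOND_CUT = -0.5           # kcal/mol
_NH_LENGTH = 0.101          # nm, reconstructed amide H


def _backbone(system: StructuredSystem, frame: Frame):
    """Per-residue backbone coordinates (N, CA, C, O, H), reconstructing H
    where missing.  Raises naming the residue if a backbone atom is absent.
    """
    resids = [int(r) for r in system.peptide_residues]
    coords = {}
    for name in ("N", "CA", "C", "O"):
        arr = np.empty((len(resids), 3))
        for k, resid in enumerate(resids):
            idx = system.peptide_residue_atoms(resid)
            hits = idx[system.name[idx] == name]
            if len(hits) == 0:
                raise MembindError(
                    f"residue {resid} is missing backbone atom {name}"
                )
            arr[k] = frame.coordinates[int(hits[0])]
        coords[name] = arr

    h = np.full((len(resids), 3), np.nan)
    for k, resid in enumerate(resids):
        idx = system.peptide_residue_atoms(resid)
        hits = idx[np.isin(system.name[idx], ("H", "HN"))]
        if len(hits):
            h[k] = frame.coordinates[int(hits[0])]
        elif k > 0:
            # standard reconstruction: along the opposed bisector of the
            # C(prev)->N and CA->N directions
            n = coords["N"][k]
            u = n - coords["C"][k - 1]
            v = n - coords["CA"][k]
            direction = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            direction /= np.linalg.norm(direction)
            h[k] = n + _NH_LENGTH * direction
    return resids, coords, h


def _ks_hbond_matrix(coords, h, resnames) -> np.ndarray:
    """hb[i, j] is True when the N-H of residue j donates to the C=O of
    residue i (Kabsch-Sander energy < -0.5 kcal/mol)."""
    n = coords["N"].shape[0]
    hb = np.zeros((n, n), dtype=bool)
    to_ang = 10.0

    for j in range(n):  # donor residue j (its N-H)
        if np.any(np.isnan(h[j])):
            continue
        if resnames is not None and resnames[j] == "PRO":
            continue
        for i in range(n):  # acceptor residue i (its C=O)
            if abs(i - j) < 1 or i == j:
                continue
            r_on = np.linalg.norm(coords["O"][i] - coords["N"][j]) * to_ang
            r_ch = np.linalg.norm(coords["C"][i] - h[j]) * to_ang
            r_oh = np.linalg.norm(coords["O"][i] - h[j]) * to_ang
            r_cn = np.linalg.norm(coords["C"][i] - coords["N"][j]) * to_ang
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9  # clash; treated as a bond like DSSP does
            else:
                energy = _KS_Q1Q2_F * (
                    1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn
                )
            if energy < _EBOND_CUT:
                hb[i, j] = True
    return hb


def assign_secstruct(
    system: StructuredSystem, frame: Frame
) -> np.ndarray:
    """Per-residue class array over the peptide residues (dtype '<U1')."""
    resids, coords, h = _backbone(system, frame)
    resnames = [
        str(system.residue_name[system.peptide_residue_atoms(r)[0]])
        for r in resids
    ]
    n = len(resids)
    hb = _ks_hbond_matrix(coords, h, resnames)

    def turn(length, i):
        return i + length < n and hb[i, i + length]

    # Bridges (Kabsch-Sander definitions), |i - j| > 2.
    parallel = np.zeros((n, n), dtype=bool)
    antiparallel = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (hb[i - 1, j] and hb[j, i + 1]) or (
                hb[j - 1, i] and hb[i, j + 1]
            ):
                parallel[i, j] = parallel[j, i] = True
            if (hb[i, j] and hb[j, i]) or (
                hb[i - 1, j + 1] and hb[j - 1, i + 1]
            ):
                antiparallel[i, j] = antiparallel[j, i] = True
    bridge = parallel | antiparallel

    # Ladders: a bridge (i, j) extends a ladder when the neighbouring
    # residue pair also bridges with the matching orientation.
    in_ladder = np.zeros(n, dtype=bool)
    has_bridge = bridge.any(axis=1)
    for i in range(n):
        for j in range(n):
            if not bridge[i, j]:
                continue
            extends = False
            if i + 1 < n and j + 1 < n and parallel[i, j] and parallel[i + 1, j + 1]:
                extends = True
            if i - 1 >= 0 and j - 1 >= 0 and parallel[i, j] and parallel[i - 1, j - 1]:
                extends = True
            if i + 1 < n and j - 1 >= 0 and antiparallel[i, j] and antiparallel[i + 1, j - 1]:
                extends = True
            if i - 1 >= 0 and j + 1 < n and antiparallel[i, j] and antiparallel[i - 1, j + 1]:
                extends = True
            if extends:
                in_ladder[i] = True

    helix4 = np.zeros(n, dtype=bool)
    helix3 = np.zeros(n, dtype=bool)
    helix5 = np.zeros(n, dtype=bool)
    for i in range(n):
        if turn(4, i) and i + 1 < n and turn(4, i + 1):
            helix4[i + 1:i + 5] = True
        if turn(3, i) and i + 1 < n and turn(3, i + 1):
            helix3[i + 1:i + 4] = True
        if turn(5, i) and i + 1 < n and turn(5, i + 1):
            helix5[i + 1:i + 6] = True

    in_turn = np.zeros(n, dtype=bool)
    for length in (3, 4, 5):
        for i in range(n):
            if turn(length, i):
                in_turn[i + 1:i + length] = True

    ss = np.full(n, "C", dtype="<U1")
    for i in range(n):
        if helix4[i]:
            ss[i] = "H"
        elif in_ladder[i]:
            ss[i] = "E"
        elif has_bridge[i]:
            ss[i] = "B"
        elif helix3[i]:
            ss[i] = "G"
        elif helix5[i]:
            ss[i] = "I"
        elif in_turn[i]:
            ss[i] = "T"
    # termini are never helix interiors
    for i in (0, n - 1):
        if ss[i] in ("H", "G", "I", "T"):
            ss[i] = "C"
    return ss


def assign_secstruct_series(traj: TrajectoryEnsemble) -> np.ndarray:
    """Stack of per-frame assignments, shape (n_frames, n_residues)."""
    return np.stack(
        [assign_secstruct(traj.topology, f) for f in traj.frames]
    )


def beta_content(assignment: np.ndarray) -> float:
    """Fraction of residues assigned extended sheet (E) in one frame."""
    assignment = np.asarray(assignment)
    return float(np.mean(assignment == "E"))


def class_fractions(assignments: np.ndarray) -> pd.DataFrame:
    """Ensemble per-residue fraction of each of the seven classes."""
    assignments = np.atleast_2d(np.asarray(assignments))
    data = {"residue_position": np.arange(1, assignments.shape[1] + 1)}
    for cls in SS_CLASSES:
        data[cls] = (assignments == cls).mean(axis=0)
    return pd.DataFrame(data)


def grouped_fractions(
    assignments: np.ndarray, partition: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Per-residue fractions of the grouped classes (unstructured = C+T+B,
    beta = E, helix = G+H+I); groups sum to 1 for every residue."""
    partition = partition or SS_GROUPS
    assignments = np.atleast_2d(np.asarray(assignments))
    data = {"residue_position": np.arange(1, assignments.shape[1] + 1)}
    for group, classes in partition.items():
        data[group] = np.isin(assignments, classes).mean(axis=0)
    return pd.DataFrame(data)
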