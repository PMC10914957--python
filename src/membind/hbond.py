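"""Geometric hydrogen-bond detection and per-residue accounting.

Criteria: heavy donor-acceptor minimum-image distance <= ``hbond_da_cutoff``
(0.3 nm default) and an angular criterion.  The default angle convention
("donor") accepts a bond when the angle between the D->H and D->A vectors is
<= ``hbond_angle_cutoff`` (20 deg); the alternative "linear" convention
instead requires the D-H...A angle at the hydrogen to be >=
``180 - hbond_angle_cutoff``.  Both cutoffs are closed (<=, >=).

Only bonds involving the peptide are reported by default; ``partner_class``
is the non-peptide side (or "peptide" for intra-peptide bonds).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .core import AnalysisConfig, Frame, MembindError, StructuredSystem, TrajectoryEnsemble
from .geometry import min_image_displacement

_DA_BOND_MAX = 0.12  # nm, covalent D-H resolution cutoff

# Peptide heavy atoms acting as acceptors, beyond the backbone carbonyl O.
_SIDECHAIN_ACCEPTOR_NAMES = {
    "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1",
}

_LIPID_ACCEPTOR_NAMES = {"O13", "O14", "O3"}

MEMBRANE_CLASSES = ("POPC", "POPS", "CHOL")
PARTNER_CLASSES = MEMBRANE_CLASSES + ("water", "peptide")

_GROUP_TO_CLASS = {
    "lipid_POPC": "POPC",
    "lipid_POPS": "POPS",
    "lipid_CHOL": "CHOL",
    "water": "water",
    "peptide": "peptide",
}


@dataclass
class DonorAcceptorTable:
    """Donor (D, H) index pairs and acceptor heavy-atom indices, resolved
    once per topology."""

    donors: np.ndarray       # shape (n_donors, 2): columns D, H
    acceptors: np.ndarray    # shape (n_acceptors,)

    @property
    def n_donors(self) -> int:
        return len(self.donors)


def _hydrogen_parents(system: StructuredSystem, frame: Frame | None):
    """Map each hydrogen index -> parent heavy index, by the site tables
    (name-based) with a coordinate fallback when a frame is supplied."""
    parents: dict[int, int] = {}
    name_rules: dict[tuple[str, str], str] = {}
    for resname, sites in chem.SIDECHAIN_SITES.items():
        for atom_name, element, parent in sites:
            if element == "H" and parent is not None:
                name_rules[(resname, atom_name)] = parent

    h_indices = np.flatnonzero(system.is_hydrogen)
    for ih in h_indices:
        resid = int(system.residue_index[ih])
        resname = str(system.residue_name[ih])
        name = str(system.name[ih])
        in_res = np.flatnonzero(
            (system.residue_index == resid)
            & (system.residue_name == resname)
            & ~system.is_hydrogen
        )
        parent_name = None
        if system.group[ih] == "peptide":
            if name in ("H", "HN", "H1", "H2", "H3"):
                parent_name = "N"
            else:
                parent_name = name_rules.get((resname, name))
        elif system.group[ih] == "water":
            ow = [i for i in in_res if str(system.name[i]).startswith("O")]
            if ow:
                parents[int(ih)] = int(ow[0])
                continue
        else:  # lipids: HN -> N, HO3 -> O3
            if name.startswith("HN"):
                parent_name = "N"
            elif name.startswith("HO"):
                parent_name = name[1:]
        if parent_name is not None:
            hits = in_res[system.name[in_res] == parent_name]
            if len(hits):
                parents[int(ih)] = int(hits[0])
                continue
        if frame is not None and len(in_res):
            d = np.linalg.norm(
                frame.coordinates[in_res] - frame.coordinates[ih], axis=1
            )
            k = int(np.argmin(d))
            if d[k] < _DA_BOND_MAX:
                parents[int(ih)] = int(in_res[k])
                continue
        raise MembindError(
            f"cannot resolve the heavy atom bonded to hydrogen "
            f"{system.serial[ih]} ({name} in {resname} {resid})"
        )
    return parents


def build_da_table(
    system: StructuredSystem,
    frame: Frame | None = None,
    config: AnalysisConfig | None = None,
) -> DonorAcceptorTable:
    """Rule-based donor/acceptor table.

    Donors are (N or O) heavy atoms with a resolvable bonded hydrogen;
    acceptors are backbone/side-chain/lipid oxygens, His ND1, water oxygen
    and (optionally, off by default) Met SD.
    """
    config = config or AnalysisConfig()
    parents = _hydrogen_parents(system, frame)

    donors = []
    for ih, id_ in sorted(parents.items()):
        if system.element[id_] in ("N", "O"):
            donors.append((id_, ih))

    acceptors = []
    for i in range(system.n_atoms):
        if system.is_hydrogen[i]:
            continue
        group = system.group[i]
        name = str(system.name[i])
        element = system.element[i]
        if group == "peptide":
            if name == "O" or name in _SIDECHAIN_ACCEPTOR_NAMES:
                acceptors.append(i)
            elif name == "SD" and config.met_sulfur_acceptor:
                acceptors.append(i)
        elif group == "water":
            if element == "O":
                acceptors.append(i)
        elif group in _GROUP_TO_CLASS:  # lipid groups
            if element == "O" and (
                name in _LIPID_ACCEPTOR_NAMES or name.startswith("O")
            ):
                acceptors.append(i)
    return DonorAcceptorTable(
        donors=np.array(sorted(donors), dtype=int).reshape(-1, 2),
        acceptors=np.array(sorted(acceptors), dtype=int),
    )


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor_residue: int
    donor_atom: str
    donor_residue_name: str
    acceptor_residue: int
    acceptor_atom: str
    acceptor_residue_name: str
    partner_class: str
    peptide_residue: int  # the peptide side of the bond


def _partner_and_peptide(system, id_, ia):
    gd = _GROUP_TO_CLASS.get(system.group[id_], "ion")
    ga = _GROUP_TO_CLASS.get(system.group[ia], "ion")
    if gd == "peptide" and ga == "peptide":
        return "peptide", int(system.residue_index[id_])
    if gd == "peptide":
        return ga, int(system.residue_index[id_])
    if ga == "peptide":
        return gd, int(system.residue_index[ia])
    return None, -1


def detect_hbonds(
    system: StructuredSystem,
    frame: Frame,
    config: AnalysisConfig,
    table: DonorAcceptorTable,
    frame_index: int = 0,
    peptide_only: bool = True,
) -> list[HBondRecord]:
    """All (D, H, A) triples satisfying the distance and angle criteria.

    Same-residue pairs are never bonds; intra-peptide bonds additionally
    require |res_D - res_A| >= 2.
    """
    if table.n_donors == 0 or len(table.acceptors) == 0:
        return []
    box = frame.box
    d_idx = table.donors[:, 0]
    h_idx = table.donors[:, 1]
    a_idx = table.acceptors
    xd = frame.coordinates[d_idx]
    xh = frame.coordinates[h_idx]
    xa = frame.coordinates[a_idx]

    disp = min_image_displacement(xd[:, None, :], xa[None, :, :], box)
    dist = np.sqrt((disp ** 2).sum(axis=-1))
    cand = dist <= config.hbond_da_cutoff

    same_res = (
        system.residue_index[d_idx][:, None] == system.residue_index[a_idx]
    ) & (
        system.group[d_idx][:, None] == system.group[a_idx]
    )
    cand &= ~same_res
    pep_d = system.peptide_mask[d_idx][:, None]
    pep_a = system.peptide_mask[a_idx][None, :]
    close_in_chain = (
        np.abs(
            system.residue_index[d_idx][:, None]
            - system.residue_index[a_idx][None, :]
        ) < 2
    )
    cand &= ~(pep_d & pep_a & close_in_chain)
    cand[np.equal(d_idx[:, None], a_idx[None, :])] = False
    if peptide_only:
        cand &= pep_d | pep_a

    records = []
    cos_cut = np.cos(np.deg2rad(config.hbond_angle_cutoff))
    for kd, ka in zip(*np.nonzero(cand)):
        id_, ih, ia = int(d_idx[kd]), int(h_idx[kd]), int(a_idx[ka])
        v_dh = min_image_displacement(frame.coordinates[id_], frame.coordinates[ih], box)
        if config.hbond_angle_convention == "donor":
            v_da = disp[kd, ka]
            cos_ang = np.dot(v_dh, v_da) / (
                np.linalg.norm(v_dh) * np.linalg.norm(v_da)
            )
            ok = cos_ang >= cos_cut - 1e-12
        else:  # linear D-H...A angle at the hydrogen
            v_hd = -v_dh
            v_ha = min_image_displacement(
                frame.coordinates[ih], frame.coordinates[ia], box
            )
            cos_ang = np.dot(v_hd, v_ha) / (
                np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
            )
            ang = np.rad2deg(np.arccos(np.clip(cos_ang, -1, 1)))
            ok = ang >= 180.0 - config.hbond_angle_cutoff - 1e-9
        if not ok:
            continue
        partner, pep_res = _partner_and_peptide(system, id_, ia)
        if partner is None and peptide_only:
            continue
        records.append(
            HBondRecord(
                frame_index=frame_index,
                donor_residue=int(system.residue_index[id_]),
                donor_atom=str(system.name[id_]),
                donor_residue_name=str(system.residue_name[id_]),
                acceptor_residue=int(system.residue_index[ia]),
                acceptor_atom=str(system.name[ia]),
                acceptor_residue_name=str(system.residue_name[ia]),
                partner_class=partner if partner is not None else "other",
                peptide_residue=pep_res,
            )
        )
    return records


@dataclass
class HBondSummary:
    """Ensemble H-bond accounting.

    ``per_residue``: mean bonds per frame for each peptide residue, one
    column per partner class plus ``membrane`` (POPC+POPS+CHOL) and the
    grand total.  ``per_frame``: total bonds per frame by aggregate class.
    """

    per_residue: pd.DataFrame
    per_frame: pd.DataFrame
    records: list[HBondRecord]


def hbond_summaries(
    traj: TrajectoryEnsemble,
    config: AnalysisConfig,
    table: DonorAcceptorTable | None = None,
) -> HBondSummary:
    if len(traj) == 0:
        raise MembindError("hbond_summaries on an empty ensemble")
    system = traj.topology
    if table is None:
        table = build_da_table(system, traj.frames[0], config)
    resids = [int(r) for r in system.peptide_residues]
    n_frames = len(traj)

    res_counts = {
        cls: {r: 0 for r in resids} for cls in PARTNER_CLASSES
    }
    frame_counts = {
        cls: np.zeros(n_frames) for cls in ("membrane", "water", "peptide")
    }
    all_records: list[HBondRecord] = []
    for fi, frame in enumerate(traj.frames):
        recs = detect_hbonds(system, frame, config, table, frame_index=fi)
        all_records.extend(recs)
        for rec in recs:
            res_counts[rec.partner_class][rec.peptide_residue] += 1
            agg = (
                "membrane" if rec.partner_class in MEMBRANE_CLASSES
                else rec.partner_class
            )
            frame_counts[agg][fi] += 1

    per_residue = pd.DataFrame(
        {
            "residue": resids,
            **{
                cls: [res_counts[cls][r] / n_frames for r in resids]
                for cls in PARTNER_CLASSES
            },
        }
    )
    per_residue["membrane"] = (
        per_residue[list(MEMBRANE_CLASSES)].sum(axis=1)
    )
    per_residue["total"] = per_residue[list(PARTNER_CLASSES)].sum(axis=1)
    per_frame = pd.DataFrame(frame_counts)
    return HBondSummary(
        per_residue=per_residue, per_frame=per_frame, records=all_records
    )


def top_hbond_types(
    records: list[HBondRecord], k: int
) -> list[tuple[tuple[str, str, str], int]]:
    """Rank (donor atom type, acceptor atom type, partner class) triples by
    frequency; ties break lexicographically."""
    if k <= 0:
        raise MembindError("k must be positive")
    if not records:
        raise MembindError("no H-bond records to rank")
    counts = Counter(
        (r.donor_atom, r.acceptor_atom, r.partner_class) for r in records
    )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
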