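"""Toy peptide builder: ideal-geometry backbone chaining, pseudo side
chains, posed beta-sheets and coil paths.

The reduced representation per residue is N, CA, C, O, amide H, a CB pseudo
side chain carrying the whole side-chain mass (absent for glycine), plus
explicit donor/acceptor sites for R, K, E, D, N, Q, H, S, T, Y, W (and Met
SD).  Bond geometry: N-CA 0.1458 nm, CA-C 0.1525 nm, C-N 0.1329 nm,
omega = 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .. import chem
from ..core import AtomRecord, MembindError

# ideal backbone internal coordinates (nm / degrees)
B_N_CA = 0.1458
B_CA_C = 0.1525
B_C_N = 0.1329
B_C_O = 0.1230
B_N_H = 0.101
A_N_CA_C = 111.0
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.5
OMEGA = 180.0

TEMPLATE_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-135.0, 135.0),
}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension (NeRF) placement of atom d from the frame a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # degenerate frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n, ca, c):
    # classic idealised CB placement; the coefficients are calibrated in
    # Angstrom, so evaluate there and convert back
    b1 = (ca - n) * 10.0
    b2 = (c - ca) * 10.0
    nv = np.cross(b1, b2)
    cb = -0.58273431 * nv + 0.56802827 * b1 - 0.54067466 * b2
    return ca + cb / 10.0


@dataclass
class BuiltPeptide:
    records: list[AtomRecord]
    coordinates: np.ndarray  # (n_atoms, 3) nm
    residue_atoms: dict[int, dict[str, int]]  # resid -> name -> atom index

    @property
    def n_atoms(self) -> int:
        return len(self.records)

    def atom(self, resid: int, name: str) -> int:
        return self.residue_atoms[resid][name]


def _coil_dihedrals(rng: np.random.Generator) -> tuple[float, float]:
    """Sample (phi, psi) from broad extended/ppII basins, avoiding the
    helical region so coils stay coil."""
    if rng.random() < 0.6:
        return rng.normal(-120.0, 20.0), rng.normal(135.0, 20.0)
    return rng.normal(-75.0, 12.0), rng.normal(150.0, 12.0)


def _resolve_dihedrals(n_res, ss_template, rng):
    if isinstance(ss_template, str):
        per_res = [ss_template] * n_res
    elif isinstance(ss_template, dict):
        per_res = ["coil"] * n_res
        for (first, last), kind in ss_template.items():
            for r in range(first, last + 1):
                per_res[r - 1] = kind
    else:
        per_res = list(ss_template)
        if len(per_res) != n_res:
            raise MembindError("per-residue template length mismatch")
    dihedrals = []
    for kind in per_res:
        if kind in TEMPLATE_DIHEDRALS:
            dihedrals.append(TEMPLATE_DIHEDRALS[kind])
        elif kind == "coil":
            if rng is None:
                dihedrals.append((-120.0, 135.0))
            else:
                dihedrals.append(_coil_dihedrals(rng))
        else:
            raise MembindError(f"unknown secondary-structure template {kind!r}")
    return dihedrals


def build_backbone(sequence: str, dihedrals) -> dict[str, np.ndarray]:
    """Chain N/CA/C/O/H positions for the given (phi, psi) list."""
    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    H = np.zeros((n_res, 3))

    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([B_N_CA, 0.0, 0.0])
    C[0] = place_atom(
        np.array([0.0, -1.0, 0.0]), N[0], CA[0], B_CA_C, A_N_CA_C, 60.0
    )
    for i in range(n_res):
        phi, psi = dihedrals[i]
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi + 180.0)
        if i + 1 < n_res:
            N[i + 1] = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi)
            CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, OMEGA)
            phi_next = dihedrals[i + 1][0]
            C[i + 1] = place_atom(
                C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phi_next
            )
    for i in range(n_res):
        if i == 0:
            u = N[0] - CA[0]
            H[0] = N[0] + B_N_H * u / np.linalg.norm(u)
        else:
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            d = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            H[i] = N[i] + B_N_H * d / np.linalg.norm(d)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def _sidechain_positions(resname, n, ca, cb):
    """Deterministic local placement of explicit side-chain sites."""
    sites = chem.SIDECHAIN_SITES.get(resname, [])
    if not sites:
        return {}
    u = cb - ca
    u = u / np.linalg.norm(u)
    ref = n - ca
    v = np.cross(u, ref)
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    positions = {}
    heavy_seen = 0
    h_per_parent: dict[str, int] = {}
    for atom_name, element, parent in sites:
        if element != "H":
            pos = (
                cb
                + u * 0.125 * (heavy_seen + 1)
                + v * 0.055 * ((-1) ** heavy_seen)
            )
            positions[atom_name] = pos
            heavy_seen += 1
        else:
            k = h_per_parent.get(parent, 0)
            h_per_parent[parent] = k + 1
            base = positions[parent]
            direction = u + 0.45 * w * ((-1) ** k) + 0.25 * v * (1 if k < 2 else -1)
            direction = direction / np.linalg.norm(direction)
            positions[atom_name] = base + 0.100 * direction
    return positions


def assemble_peptide(
    sequence: str, backbone: dict[str, np.ndarray], start_serial: int = 1
) -> BuiltPeptide:
    """Turn backbone arrays into records + coordinates, adding CB pseudo
    side chains and explicit donor/acceptor sites."""
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    residue_atoms: dict[int, dict[str, int]] = {}
    serial = start_serial
    for i, letter in enumerate(sequence):
        if letter not in chem.AA_1TO3:
            raise MembindError(f"unknown residue letter {letter!r}")
        resname = chem.AA_1TO3[letter]
        resid = i + 1
        residue_atoms[resid] = {}

        def add(name, element, pos, mass=None):
            nonlocal serial
            records.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    mass=mass if mass is not None else chem.ELEMENT_MASS[element],
                    residue_index=resid,
                    residue_name=resname,
                    group="peptide",
                )
            )
            coords.append(np.asarray(pos, dtype=float))
            residue_atoms[resid][name] = len(records) - 1
            serial += 1

        add("N", "N", backbone["N"][i])
        add("H", "H", backbone["H"][i])
        add("CA", "C", backbone["CA"][i])
        add("C", "C", backbone["C"][i])
        add("O", "O", backbone["O"][i])
        if resname != "GLY":
            cb = _cb_position(
                backbone["N"][i], backbone["CA"][i], backbone["C"][i]
            )
            add("CB", "C", cb, mass=chem.SIDECHAIN_MASS[resname])
            for name, pos in _sidechain_positions(
                resname, backbone["N"][i], backbone["CA"][i], cb
            ).items():
                element = next(
                    el for nm, el, _ in chem.SIDECHAIN_SITES[resname]
                    if nm == name
                )
                add(name, element, pos)
    return BuiltPeptide(
        records=records,
        coordinates=np.array(coords),
        residue_atoms=residue_atoms,
    )


def build_peptide(
    sequence: str,
    ss_template="coil",
    seed: int | None = None,
) -> BuiltPeptide:
    """Build a peptide with template dihedrals.

    ``ss_template`` is a single kind ('helix' | 'strand' | 'coil'), a
    per-residue list of kinds, or a dict {(first, last): kind} with 1-based
    inclusive residue ranges (unlisted residues are coil).
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    dihedrals = _resolve_dihedrals(len(sequence), ss_template, rng)
    backbone = build_backbone(sequence, dihedrals)
    return assemble_peptide(sequence, backbone)


# ---------------------------------------------------------------------------
# posed conformers: rigid segments + connecting paths


def _apply_rigid(coords, rotvec, translation):
    rot = Rotation.from_rotvec(rotvec)
    return rot.apply(coords) + translation


def pose_antiparallel_strand(
    bb_fixed: dict[str, np.ndarray],
    fixed_residues: list[int],
    bb_mobile: dict[str, np.ndarray],
    mobile_residues: list[int],
    target_no: float = 0.29,
):
    """Rigid transform (rotvec, translation) posing the mobile strand
    antiparallel against the fixed one so that registry residues form
    mutual N-H...O=C pairs satisfying the Kabsch-Sander criterion.

    ``fixed_residues``/``mobile_residues`` are 0-based indices into the
    respective backbone arrays, already matched one-to-one (first fixed
    pairs with first mobile).
    """
    fa = np.array(fixed_residues, dtype=int)
    ma = np.array(mobile_residues, dtype=int)

    axis_f = bb_fixed["CA"][fa[-1]] - bb_fixed["CA"][fa[0]]
    axis_f = axis_f / np.linalg.norm(axis_f)
    nh_f = bb_fixed["H"][fa] - bb_fixed["N"][fa]
    h_dir = nh_f.mean(axis=0)
    h_dir = h_dir - axis_f * np.dot(h_dir, axis_f)
    h_dir = h_dir / np.linalg.norm(h_dir)

    axis_m = bb_mobile["CA"][ma[-1]] - bb_mobile["CA"][ma[0]]
    axis_m = axis_m / np.linalg.norm(axis_m)
    nh_m = bb_mobile["H"][ma] - bb_mobile["N"][ma]
    h_dir_m = nh_m.mean(axis=0)
    h_dir_m = h_dir_m - axis_m * np.dot(h_dir_m, axis_m)
    h_dir_m = h_dir_m / np.linalg.norm(h_dir_m)

    # initial guess: mobile axis -> -fixed axis, mobile NH -> -fixed NH
    frame_f = np.column_stack(
        [-axis_f, -h_dir, np.cross(-axis_f, -h_dir)]
    )
    frame_m = np.column_stack(
        [axis_m, h_dir_m, np.cross(axis_m, h_dir_m)]
    )
    r0 = Rotation.from_matrix(frame_f @ frame_m.T)
    center_target = (
        bb_fixed["N"][fa].mean(axis=0) + (target_no + 0.05) * h_dir
    )
    t0 = center_target - r0.apply(bb_mobile["N"][ma].mean(axis=0))

    n_f = bb_fixed["N"][fa]
    o_f = bb_fixed["O"][fa]
    h_f = bb_fixed["H"][fa]
    n_m = bb_mobile["N"][ma]
    o_m = bb_mobile["O"][ma]
    h_m = bb_mobile["H"][ma]

    def residuals(params):
        rot = Rotation.from_rotvec(params[:3]) * r0
        t = params[3:] + t0
        nm = rot.apply(n_m) + t
        om = rot.apply(o_m) + t
        hm = rot.apply(h_m) + t
        res = []
        # mutual rungs: N(fixed) -> O(mobile) and N(mobile) -> O(fixed)
        res.append(np.linalg.norm(n_f - om, axis=1) - target_no)
        res.append(np.linalg.norm(nm - o_f, axis=1) - target_no)
        # alignment: the N->H bond should point at the partner O
        for n_arr, h_arr, o_arr in ((n_f, h_f, om), (nm, hm, o_f)):
            v_no = o_arr - n_arr
            v_nh = h_arr - n_arr
            cosang = np.sum(v_no * v_nh, axis=1) / (
                np.linalg.norm(v_no, axis=1) * np.linalg.norm(v_nh, axis=1)
            )
            res.append(0.15 * (1.0 - cosang))
        return np.concatenate(res)

    sol = least_squares(residuals, np.zeros(6), method="lm", max_nfev=2000)
    rot = Rotation.from_rotvec(sol.x[:3]) * r0
    t = sol.x[3:] + t0
    return rot, t


def path_backbone(ca_path: np.ndarray, lift=None) -> dict[str, np.ndarray]:
    """Backbone atoms placed around prescribed CA positions.

    The local frame per residue comes from the path tangent; a 'lift'
    direction (default +z) orients carbonyls/amides.  Used for loops,
    dangling tails and coil-dominated conformers where hydrogen-bond
    patterns are deliberately absent.
    """
    ca = np.asarray(ca_path, dtype=float)
    n = len(ca)
    if lift is None:
        lift = np.array([0.0, 0.0, 1.0])
    N = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    H = np.zeros((n, 3))
    for i in range(n):
        if n == 1:
            t = np.array([1.0, 0.0, 0.0])
        elif i == 0:
            t = ca[1] - ca[0]
        elif i == n - 1:
            t = ca[-1] - ca[-2]
        else:
            t = ca[i + 1] - ca[i - 1]
        t = t / np.linalg.norm(t)
        side = np.cross(t, lift)
        ns = np.linalg.norm(side)
        if ns < 1e-8:
            side = np.cross(t, np.array([1.0, 0.0, 0.0]))
            ns = np.linalg.norm(side)
        side /= ns
        up = np.cross(side, t)
        flip = 1.0 if i % 2 == 0 else -1.0
        N[i] = ca[i] - 0.1458 * t + 0.02 * flip * up
        C[i] = ca[i] + 0.1525 * t + 0.02 * flip * up
        O[i] = C[i] + B_C_O * flip * up
        H[i] = N[i] - B_N_H * flip * up
    return {"N": N, "CA": ca.copy(), "C": C, "O": O, "H": H}


def merge_backbones(
    n_res: int, pieces: list[tuple[range, dict[str, np.ndarray]]]
) -> dict[str, np.ndarray]:
    """Stitch residue-range backbone pieces into full-length arrays.

    ``pieces`` must cover 1..n_res exactly once (1-based inclusive ranges
    expressed as ``range(first, last + 1)``).
    """
    out = {k: np.full((n_res, 3), np.nan) for k in ("N", "CA", "C", "O", "H")}
    seen = np.zeros(n_res, dtype=bool)
    for rng_, bb in pieces:
        idx = np.array(list(rng_)) - 1
        if np.any(seen[idx]):
            raise MembindError("backbone pieces overlap")
        seen[idx] = True
        for key in out:
            out[key][idx] = bb[key][: len(idx)] if len(bb[key]) != len(idx) else bb[key]
    if not np.all(seen):
        missing = np.flatnonzero(~seen) + 1
        raise MembindError(f"backbone pieces miss residues {missing.tolist()}")
    return out


def bezier_path(p0, p1, apex_lift, n_points: int) -> np.ndarray:
    """Quadratic Bezier CA path between two anchors with a lifted apex."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    mid = 0.5 * (p0 + p1) + np.asarray(apex_lift, dtype=float)
    t = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    return (
        (1 - t)[:, None] ** 2 * p0
        + 2 * ((1 - t) * t)[:, None] * mid
        + (t**2)[:, None] * p1
    )


def segment_strand(n_res: int) -> dict[str, np.ndarray]:
    """An isolated ideal strand segment at the origin (template dihedrals)."""
    seq = "A" * n_res
    return build_backbone(seq, [TEMPLATE_DIHEDRALS["strand"]] * n_res)


def segment_helix(n_res: int) -> dict[str, np.ndarray]:
    seq = "A" * n_res
    return build_backbone(seq, [TEMPLATE_DIHEDRALS["helix"]] * n_res)


def transform_backbone(bb, rot: Rotation, t) -> dict[str, np.ndarray]:
    return {k: rot.apply(v) + t for k, v in bb.items()}


def principal_axis(bb) -> np.ndarray:
    ca = bb["CA"]
    axis = ca[-1] - ca[0]
    return axis / np.linalg.norm(axis)


def build_hairpin(
    sequence: str,
    strand1: tuple[int, int],
    strand2: tuple[int, int],
) -> BuiltPeptide:
    """Antiparallel beta-hairpin: two posed strands joined by a turn.

    ``strand1``/``strand2`` are 1-based inclusive residue ranges of equal
    length, separated by >= 1 turn residue; residue i of strand1 pairs with
    the mirrored residue of strand2.
    """
    (a0, a1), (b0, b1) = strand1, strand2
    n1, n2 = a1 - a0 + 1, b1 - b0 + 1
    if n1 != n2:
        raise MembindError("hairpin strands must have equal length")
    if b0 <= a1 + 1:
        raise MembindError("hairpin strands need at least one turn residue")
    s1 = align_segment(
        segment_strand(n1), [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]
    )
    s2_seg = segment_strand(n2)
    # mutual rungs every other residue, starting from the strand1 end
    fixed_idx = list(range(n1 - 1, -1, -2))
    mobile_idx = [(n1 - 1 - k) for k in fixed_idx]
    rot, t = pose_antiparallel_strand(s1, fixed_idx, s2_seg, mobile_idx)
    s2 = transform_backbone(s2_seg, rot, t)

    pieces: list[tuple[range, dict[str, np.ndarray]]] = [
        (range(a0, a1 + 1), s1),
        (range(b0, b1 + 1), s2),
    ]
    n_turn = b0 - a1 - 1
    turn = bezier_path(s1["CA"][-1], s2["CA"][0], [0.3, 0.3, 0.4], n_turn)
    pieces.append((range(a1 + 1, b0), path_backbone(turn)))
    if a0 > 1:
        lead = s1["CA"][0] - np.outer(
            np.arange(a0 - 1, 0, -1) * 0.36, np.array([0.95, 0.25, 0.15])
        )
        pieces.append((range(1, a0), path_backbone(lead)))
    n_res = len(sequence)
    if b1 < n_res:
        tail = s2["CA"][-1] + np.outer(
            np.arange(1, n_res - b1 + 1) * 0.36, np.array([0.95, 0.25, 0.15])
        )
        pieces.append((range(b1 + 1, n_res + 1), path_backbone(tail)))
    bb = merge_backbones(n_res, pieces)
    return assemble_peptide(sequence, bb)


def align_segment(bb, axis_target, origin, flip_reference=None):
    """Rotate a segment so its CA axis matches ``axis_target`` and its first
    CA sits at ``origin``; deterministic roll."""
    axis = principal_axis(bb)
    axis_target = np.asarray(axis_target, dtype=float)
    axis_target = axis_target / np.linalg.norm(axis_target)
    v = np.cross(axis, axis_target)
    s = np.linalg.norm(v)
    c = np.dot(axis, axis_target)
    if s < 1e-10:
        rot = Rotation.identity() if c > 0 else Rotation.from_rotvec(
            np.pi * np.array([0.0, 0.0, 1.0])
        )
    else:
        rot = Rotation.from_rotvec(v / s * np.arctan2(s, c))
    moved = transform_backbone(bb, rot, np.zeros(3))
    t = np.asarray(origin, dtype=float) - moved["CA"][0]
    return transform_backbone(moved, Rotation.identity(), t)
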