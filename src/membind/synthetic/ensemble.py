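"""Ground-truth trajectory generator.

Builds posed peptide conformers matching the four binding-model templates
(beta-sheet stacks, surface helices, buried coils), places them against a
pseudo-lipid bilayer with per-frame rigid-body jitter, plants hydrogen
bonds by posing acceptor lipids/waters, and emits the planted truth next to
the frames.  Everything is driven by a single seeded RNG stream, so equal
seeds give bit-identical ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .. import chem
from ..core import (
    AtomRecord,
    Frame,
    MembindError,
    TrajectoryEnsemble,
    build_system,
)
from . import peptide as pep
from .bilayer import BuiltBilayer, build_bilayer

BOX_Z = 16.0
MODEL_TEMPLATES = ("model1", "model2", "model3", "model4", "unbound")

# default planted H-bond pairs (peptide residue, partner class) per template
_DEFAULT_PLANTS = {
    "model1": [],
    "model2": [(5, "POPS")],
    "model3": [(5, "POPS"), (16, "POPC")],
    "model4": [(16, "POPC"), (28, "POPS")],
    "unbound": [],
}

_DEFAULT_SS = {
    "model1": {"NT": "strand", "CHC": "strand", "CL": "coil", "CT": "strand"},
    "model2": {"NT": "helix", "CHC": "coil", "CL": "coil", "CT": "coil"},
    "model3": {"NT": "strand", "CHC": "strand", "CL": "strand", "CT": "coil"},
    "model4": {"NT": "coil", "CHC": "coil", "CL": "coil", "CT": "coil"},
    "unbound": {"NT": "coil", "CHC": "coil", "CL": "coil", "CT": "coil"},
}

_DEFAULT_DEPTHS = {
    "model1": {"NT": 0.79, "CHC": 0.32, "CL": 0.5, "CT": -0.15},
    "model2": {"NT": 0.15, "CHC": 0.6, "CL": 1.0, "CT": 1.2},
    "model3": {"NT": 1.19, "CHC": 0.72, "CL": 0.25, "CT": -0.7},
    "model4": {"NT": 1.0, "CHC": -0.5, "CL": 0.5, "CT": -0.5},
    "unbound": {"NT": 3.0, "CHC": 3.0, "CL": 3.0, "CT": 3.0},
}


@dataclass
class SyntheticSpec:
    """Planted ground truth for one generated ensemble."""

    seed: int
    n_frames: int
    model_template: str = "model3"
    mixture_weights: dict[str, float] | None = None
    sequence: str = chem.ABETA40_SEQUENCE
    region_ss: dict[str, str] | None = None
    region_depths: dict[str, float] | None = None
    planted_hbonds: list[tuple[int, str]] | None = None
    distance_means: tuple[float, ...] = (2.65, 3.45)
    distance_sds: tuple[float, ...] = (0.08, 0.08)
    distance_weights: tuple[float, ...] = (0.5, 0.5)
    unbound_distance_mean: float = 5.0
    unbound_distance_sd: float = 0.15
    n_waters: int = 8
    noise_sigma: float = 0.05
    frame_spacing: float = 1.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise MembindError("n_frames must be >= 1")
        if self.model_template not in MODEL_TEMPLATES + ("mixture",):
            raise MembindError(
                f"unknown model template {self.model_template!r}"
            )
        if self.model_template == "mixture":
            if not self.mixture_weights:
                raise MembindError("mixture template needs mixture_weights")
            total = sum(self.mixture_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise MembindError("mixture weights must sum to 1")
        if abs(sum(self.distance_weights) - 1.0) > 1e-9:
            raise MembindError("distance weights must sum to 1")
        if any(s <= 0 for s in self.distance_sds):
            raise MembindError("distance sds must be positive")
        depths = self.region_depths or {}
        for label, depth in depths.items():
            if depth < -2.0:
                raise MembindError(
                    f"region {label} target depth {depth} is deeper than the "
                    "membrane half thickness"
                )


def polyline_path(waypoints, n_points: int) -> np.ndarray:
    """n CA positions at even arc length along a polyline."""
    wp = np.asarray(waypoints, dtype=float)
    seg = np.diff(wp, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.linspace(0.0, cum[-1], n_points)
    out = np.empty((n_points, 3))
    for k, sk in enumerate(s):
        i = min(np.searchsorted(cum, sk, side="right") - 1, len(seg) - 1)
        f = (sk - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        out[k] = wp[i] + f * seg[i]
    return out


def _orient_sheet(pieces: list[dict[str, np.ndarray]]):
    """Rotate a stack of posed strands so the stacking direction is -z and
    the first strand runs along +x; returns transformed pieces."""
    first, last = pieces[0], pieces[-1]
    stack_dir = last["CA"].mean(axis=0) - first["CA"].mean(axis=0)
    stack_dir /= np.linalg.norm(stack_dir)
    axis = pep.principal_axis(first)
    axis = axis - stack_dir * np.dot(axis, stack_dir)
    axis /= np.linalg.norm(axis)
    target = np.column_stack(
        [np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0]),
         np.cross([1.0, 0.0, 0.0], [0.0, 0.0, -1.0])]
    )
    source = np.column_stack([axis, stack_dir, np.cross(axis, stack_dir)])
    rot = Rotation.from_matrix(target @ source.T)
    return [pep.transform_backbone(p, rot, np.zeros(3)) for p in pieces]


def _shift_pieces(pieces, dz):
    return [
        {k: v + np.array([0.0, 0.0, dz]) for k, v in p.items()}
        for p in pieces
    ]


def _line_path(start, direction, n, spacing=0.36):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return np.asarray(start) + np.outer(
        np.arange(1, n + 1) * spacing, direction
    )


def _sheet_conformer(strand_ranges, registries, z_targets, surface_z):
    """Pose antiparallel strand stack.

    ``strand_ranges``: [(first, last), ...] 1-based residue ranges;
    ``registries``: [(fixed_idx_list, mobile_idx_list), ...] pairing each
    strand k+1 against strand k; ``z_targets``: CA-plane z per strand
    relative to the surface.  Returns posed backbone pieces (one per
    strand) in the membrane frame.
    """
    segs = [pep.segment_strand(last - first + 1) for first, last in strand_ranges]
    posed = [pep.align_segment(segs[0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0])]
    for k, (fixed_idx, mobile_idx) in enumerate(registries):
        rot, t = pep.pose_antiparallel_strand(
            posed[k], fixed_idx, segs[k + 1], mobile_idx
        )
        posed.append(pep.transform_backbone(segs[k + 1], rot, t))
    posed = _orient_sheet(posed)
    # place strand 0 at its target height; the pose fixes the others
    dz = (surface_z + z_targets[0]) - posed[0]["CA"][:, 2].mean()
    posed = _shift_pieces(posed, dz)
    return posed


def _conformer_model1(sequence, surface_z, rng):
    s_ranges = [(4, 10), (17, 21), (33, 36)]
    registries = [
        ([6, 4, 2], [0, 2, 4]),   # res 10<->17, 8<->19, 6<->21
        ([3, 1], [1, 3]),         # res 20<->34, 18<->36
    ]
    posed = _sheet_conformer(
        s_ranges, registries, [0.97], surface_z
    )
    pieces = [
        (range(4, 11), posed[0]),
        (range(17, 22), posed[1]),
        (range(33, 37), posed[2]),
    ]
    # leading tail, inter-strand loops, trailing tail; loops arc away from
    # the sheet with carbonyls oriented sideways so no spurious ladders form
    y_lift = np.array([0.0, 1.0, 0.0])
    ca4, ca10 = posed[0]["CA"][0], posed[0]["CA"][-1]
    ca17, ca21 = posed[1]["CA"][0], posed[1]["CA"][-1]
    ca33, ca36 = posed[2]["CA"][0], posed[2]["CA"][-1]
    tail_n = _line_path(ca4, [-1.0, 0.3, 0.25], 3)[::-1]
    pieces.append((range(1, 4), pep.path_backbone(tail_n)))
    loop_a = pep.bezier_path(ca10, ca17, [0.4, 1.0, 0.9], 6)
    pieces.append((range(11, 17), pep.path_backbone(loop_a, lift=y_lift)))
    loop_b = polyline_path(
        [
            ca21,
            ca21 + np.array([0.1, 0.72, 0.6]),
            ca21 + np.array([-0.6, 1.2, 1.08]),
            ca33 + np.array([-1.2, 1.08, 1.08]),
            ca33 + np.array([-0.72, 0.48, 0.48]),
            ca33,
        ],
        13,
    )[1:-1]
    pieces.append((range(22, 33), pep.path_backbone(loop_b, lift=y_lift)))
    tail_c = _line_path(ca36, [0.6, 0.3, 1.0], 4)
    pieces.append((range(37, 41), pep.path_backbone(tail_c)))
    return pep.merge_backbones(len(sequence), pieces)


def _conformer_model3(sequence, surface_z, rng):
    s_ranges = [(5, 7), (17, 20), (23, 26)]
    registries = [
        ([2, 0], [0, 2]),  # res 7<->17, 5<->19
        ([3, 1], [0, 2]),  # res 20<->23, 18<->25
    ]
    posed = _sheet_conformer(s_ranges, registries, [1.19], surface_z)
    pieces = [
        (range(5, 8), posed[0]),
        (range(17, 21), posed[1]),
        (range(23, 27), posed[2]),
    ]
    y_lift = np.array([0.0, 1.0, 0.0])
    ca5, ca7 = posed[0]["CA"][0], posed[0]["CA"][-1]
    ca17, ca20 = posed[1]["CA"][0], posed[1]["CA"][-1]
    ca23, ca26 = posed[2]["CA"][0], posed[2]["CA"][-1]
    tail_n = _line_path(ca5, [-1.0, 0.4, 0.1], 4)[::-1]
    pieces.append((range(1, 5), pep.path_backbone(tail_n)))
    loop_a = pep.bezier_path(ca7, ca17, [0.3, 2.0, 0.8], 9)
    pieces.append((range(8, 17), pep.path_backbone(loop_a, lift=y_lift)))
    loop_b = pep.bezier_path(ca20, ca23, [-0.6, 0.7, 0.2], 2)
    pieces.append((range(21, 23), pep.path_backbone(loop_b, lift=y_lift)))
    # CT tail dives below the surface
    start = ca26 + np.array([0.3, 0.0, 0.0])
    ct_path = polyline_path(
        [
            start,
            start + np.array([0.9, 0.1, -0.5]),
            start + np.array([1.8, 0.3, -1.1]),
            start + np.array([1.4, 1.3, -1.55]),
            start + np.array([0.4, 1.7, -1.75]),
        ],
        14,
    )
    ct_path[:, 2] = np.maximum(ct_path[:, 2], surface_z - 1.8)
    pieces.append((range(27, 41), pep.path_backbone(ct_path)))
    return pep.merge_backbones(len(sequence), pieces)


def _conformer_model2(sequence, surface_z, rng):
    helix_a = pep.align_segment(
        pep.segment_helix(8), [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]
    )
    dz_a = (surface_z + 0.06) - helix_a["CA"][:, 2].min()
    helix_a = {k: v + np.array([0.0, 0.0, dz_a]) for k, v in helix_a.items()}
    helix_b = pep.align_segment(
        pep.segment_helix(6), [1.0, 0.0, 0.0], [0.0, 0.9, 0.0]
    )
    dz_b = (surface_z + 0.55) - helix_b["CA"][:, 2].min()
    helix_b = {k: v + np.array([0.0, 0.0, dz_b]) for k, v in helix_b.items()}

    pieces = [(range(2, 10), helix_a), (range(11, 17), helix_b)]
    ca2, ca9 = helix_a["CA"][0], helix_a["CA"][-1]
    ca11, ca16 = helix_b["CA"][0], helix_b["CA"][-1]
    pieces.append(
        (range(1, 2), pep.path_backbone(_line_path(ca2, [-1.0, 0.2, 0.3], 1)))
    )
    bridge = pep.bezier_path(ca9, ca11, [0.1, 0.3, 0.35], 1)
    pieces.append((range(10, 11), pep.path_backbone(bridge)))
    start = ca16 + np.array([0.3, 0.0, 0.3])
    rest = polyline_path(
        [
            start,
            start + np.array([0.6, 0.4, 0.7]),
            start + np.array([2.6, 0.6, 1.1]),
            start + np.array([2.8, 1.5, 1.2]),
            start + np.array([0.4, 1.7, 1.2]),
            start + np.array([0.2, 2.6, 1.2]),
            start + np.array([2.4, 2.8, 1.2]),
        ],
        24,
    )
    pieces.append((range(17, 41), pep.path_backbone(rest)))
    return pep.merge_backbones(len(sequence), pieces)


def _conformer_model4(sequence, surface_z, rng):
    s = surface_z

    def at(x, y, depth):
        return np.array([x, y, s + depth])

    nt = polyline_path(
        [at(0.0, 0.0, 1.0), at(2.4, 0.2, 1.0), at(2.7, 1.0, 1.0),
         at(0.6, 1.2, 1.0), at(0.2, 1.6, 0.9)],
        12,
    )
    descend1 = polyline_path(
        [nt[-1] + np.array([0.3, 0.2, -0.3]), at(1.4, 2.0, -0.5)], 4
    )
    chc = polyline_path(
        [descend1[-1] + np.array([0.35, 0.0, 0.0]),
         at(3.2, 2.1, -0.5)], 5
    )
    cl = pep.bezier_path(chc[-1], at(1.2, 2.9, -0.45), [0.2, 0.4, 1.1], 8)
    ct = polyline_path(
        [at(0.9, 3.0, -0.5), at(-0.9, 3.1, -0.55), at(-1.3, 3.8, -0.5),
         at(0.8, 3.9, -0.5)],
        11,
    )
    pieces = [
        (range(1, 13), pep.path_backbone(nt)),
        (range(13, 17), pep.path_backbone(descend1)),
        (range(17, 22), pep.path_backbone(chc)),
        (range(22, 30), pep.path_backbone(cl)),
        (range(30, 41), pep.path_backbone(ct)),
    ]
    return pep.merge_backbones(len(sequence), pieces)


def _conformer_unbound(sequence, surface_z, rng):
    # compact serpentine well above the membrane; z offset applied later
    rows = []
    z0 = surface_z + 3.0
    for r in range(4):
        x0, x1 = (0.0, 3.2) if r % 2 == 0 else (3.2, 0.0)
        rows.append(np.array([x0, 0.85 * r, z0 + 0.15 * (r % 2)]))
        rows.append(np.array([x1, 0.85 * r + 0.3, z0 + 0.1]))
    path = polyline_path(rows, len(sequence))
    jitter = rng.normal(0.0, 0.03, size=path.shape)
    return pep.path_backbone(path + jitter)


_CONFORMER_BUILDERS = {
    "model1": _conformer_model1,
    "model2": _conformer_model2,
    "model3": _conformer_model3,
    "model4": _conformer_model4,
    "unbound": _conformer_unbound,
}


def build_template_conformer(
    template: str, sequence: str, surface_z: float, rng
) -> pep.BuiltPeptide:
    try:
        builder = _CONFORMER_BUILDERS[template]
    except KeyError:
        raise MembindError(f"unknown template {template!r}") from None
    backbone = builder(sequence, surface_z, rng)
    return pep.assemble_peptide(sequence, backbone)


def _donor_site(built: pep.BuiltPeptide, resid: int, sequence: str):
    """(D, H) atom names for planting at a residue: side-chain donor when
    the residue has one, else the backbone amide."""
    resname = chem.AA_1TO3[sequence[resid - 1]]
    for atom_name, element, parent in chem.SIDECHAIN_SITES.get(resname, []):
        if element == "H" and parent is not None:
            return parent, atom_name
    return "N", "H"


_PLANT_ACCEPTOR = {"POPC": "O13", "POPS": "O13", "CHOL": "O3", "water": "OW"}


def _water_records(n_waters, start_serial, start_residue):
    records = []
    serial, resid = start_serial, start_residue
    for _ in range(n_waters):
        for name, element in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            records.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    mass=chem.ELEMENT_MASS[element],
                    residue_index=resid,
                    residue_name="TIP3",
                    group="water",
                )
            )
            serial += 1
        resid += 1
    return records


def _water_base_coords(n_waters, bilayer: BuiltBilayer, rng):
    coords = np.zeros((n_waters * 3, 3))
    top = bilayer.center_z + bilayer.half_thickness
    for w in range(n_waters):
        o = np.array(
            [
                rng.uniform(0, bilayer.box_xy[0]),
                rng.uniform(0, bilayer.box_xy[1]),
                top + rng.uniform(1.6, 2.4),
            ]
        )
        coords[3 * w] = o
        coords[3 * w + 1] = o + np.array([0.096, 0.0, 0.0])
        coords[3 * w + 2] = o + np.array([-0.024, 0.093, 0.0])
    return coords


def _frame_labels(spec: SyntheticSpec, rng) -> list[str]:
    if spec.model_template != "mixture":
        return [spec.model_template] * spec.n_frames
    labels = []
    items = sorted(spec.mixture_weights.items())
    counts = {k: int(np.floor(w * spec.n_frames)) for k, w in items}
    remainder = spec.n_frames - sum(counts.values())
    fracs = sorted(
        items, key=lambda kv: -(kv[1] * spec.n_frames - np.floor(kv[1] * spec.n_frames))
    )
    for k, _ in fracs[:remainder]:
        counts[k] += 1
    for k, _ in items:
        labels.extend([k] * counts[k])
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


@dataclass
class GroundTruth:
    seed: int
    model_template: str
    frame_labels: list[str]
    bound: list[bool]
    region_ss: dict[str, dict[str, str]]
    region_depths: dict[str, dict[str, float]]
    planted_hbonds: dict[str, list[tuple[int, str]]]
    unbound_distances: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["unbound_distances"] = {
            str(k): v for k, v in self.unbound_distances.items()
        }
        return d


def generate_binding_ensemble(
    spec: SyntheticSpec,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Generate frames with planted structure/depth/H-bond ground truth."""
    rng = np.random.default_rng(spec.seed)
    bilayer = build_bilayer(seed=int(rng.integers(2**31)))
    surface_top = bilayer.center_z + bilayer.half_thickness
    box = np.array([bilayer.box_xy[0], bilayer.box_xy[1], BOX_Z])

    labels = _frame_labels(spec, rng)
    needed = sorted(set(labels))
    conformers: dict[str, pep.BuiltPeptide] = {}
    for template in needed:
        backbone = _CONFORMER_BUILDERS[template](
            spec.sequence, surface_top, rng
        )
        conformers[template] = pep.assemble_peptide(spec.sequence, backbone)

    base = conformers[needed[0]]
    n_pep = base.n_atoms
    lipid_records = [
        AtomRecord(
            serial=r.serial + n_pep,
            name=r.name,
            element=r.element,
            mass=r.mass,
            residue_index=r.residue_index + 40,
            residue_name=r.residue_name,
            group=r.group,
        )
        for r in bilayer.records
    ]
    n_lipid_atoms = len(lipid_records)
    water_records = _water_records(
        spec.n_waters, n_pep + n_lipid_atoms + 1,
        41 + len({r.residue_index for r in bilayer.records}),
    )
    records = list(base.records) + lipid_records + water_records
    system = build_system(records)
    water_base = _water_base_coords(spec.n_waters, bilayer, rng)

    # planted H-bond bookkeeping: dedicate one partner molecule per pair
    plants: dict[str, list[tuple[int, str]]] = {}
    for template in needed:
        plants[template] = (
            spec.planted_hbonds
            if spec.planted_hbonds is not None
            else _DEFAULT_PLANTS[template]
        )
    lipid_resids_by_class: dict[str, list[int]] = {"POPC": [], "POPS": [], "CHOL": []}
    lipid_res_z: dict[int, float] = {}
    for r, c in zip(bilayer.records, bilayer.coordinates):
        lipid_res_z.setdefault(r.residue_index + 40, c[2])
    for r in lipid_records:
        cls = r.residue_name if r.residue_name != "CHL1" else "CHOL"
        if cls in lipid_resids_by_class and r.residue_index not in (
            lipid_resids_by_class[cls]
        ):
            if lipid_res_z[r.residue_index] > bilayer.center_z:
                lipid_resids_by_class[cls].append(r.residue_index)

    partner_assignment: dict[tuple[int, str], int] = {}
    used_by_class = {"POPC": 0, "POPS": 0, "CHOL": 0, "water": 0}
    for template in needed:
        for resid, cls in plants[template]:
            key = (resid, cls)
            if key in partner_assignment:
                continue
            if cls == "water":
                idx = used_by_class["water"]
                if idx >= spec.n_waters:
                    raise MembindError("not enough waters for planted bonds")
                partner_assignment[key] = idx
            else:
                pool = lipid_resids_by_class[cls]
                idx = used_by_class[cls]
                if idx >= len(pool):
                    raise MembindError(f"not enough {cls} lipids to plant")
                partner_assignment[key] = pool[idx]
            used_by_class[cls] += 1

    lipid_coords0 = bilayer.coordinates
    frames = []
    truth = GroundTruth(
        seed=spec.seed,
        model_template=spec.model_template,
        frame_labels=labels,
        bound=[lab != "unbound" for lab in labels],
        region_ss={
            t: (spec.region_ss or _DEFAULT_SS[t]) for t in needed
        },
        region_depths={
            t: (spec.region_depths or _DEFAULT_DEPTHS[t]) for t in needed
        },
        planted_hbonds=plants,
    )

    pep_center_xy = np.array(
        [bilayer.box_xy[0] / 2 - 1.5, bilayer.box_xy[1] / 2 - 1.5, 0.0]
    )
    for fi, label in enumerate(labels):
        conf = conformers[label]
        coords_pep = conf.coordinates.copy()
        com = coords_pep.mean(axis=0)
        angle = rng.normal(0.0, np.deg2rad(5.0))
        rot = Rotation.from_rotvec([0.0, 0.0, angle])
        coords_pep = rot.apply(coords_pep - com) + com
        jitter = np.array(
            [
                rng.normal(0.0, spec.noise_sigma),
                rng.normal(0.0, spec.noise_sigma),
                rng.normal(0.0, spec.noise_sigma),
            ]
        )
        coords_pep = coords_pep + jitter + pep_center_xy

        if label == "unbound":
            target = rng.normal(
                spec.unbound_distance_mean, spec.unbound_distance_sd
            )
            target = float(max(target, 3.5))
            masses = system.mass[: n_pep]
            com_z = float(
                (coords_pep[:, 2] * masses).sum() / masses.sum()
            )
            coords_pep[:, 2] += (bilayer.center_z + target) - com_z
            truth.unbound_distances[fi] = target

        lipid_coords = lipid_coords0.copy()
        waters = water_base + rng.normal(
            0.0, spec.noise_sigma, size=water_base.shape
        ) * 0.2

        # plant H-bonds by posing the dedicated partner's acceptor atom
        for resid, cls in plants[label]:
            d_name, h_name = _donor_site(base, resid, spec.sequence)
            di = conf.atom(resid, d_name)
            hi = conf.atom(resid, h_name)
            d_pos, h_pos = coords_pep[di], coords_pep[hi]
            direction = h_pos - d_pos
            direction /= np.linalg.norm(direction)
            target_pos = d_pos + 0.28 * direction
            acc_name = _PLANT_ACCEPTOR[cls]
            if cls == "water":
                w = partner_assignment[(resid, cls)]
                delta = target_pos - waters[3 * w]
                waters[3 * w: 3 * w + 3] += delta
            else:
                lr = partner_assignment[(resid, cls)]
                mask = np.array(
                    [r.residue_index == lr for r in lipid_records]
                )
                names = np.array([r.name for r in lipid_records])
                acc_local = np.flatnonzero(mask & (names == acc_name))[0]
                delta = target_pos - lipid_coords[acc_local]
                lipid_coords[mask] += delta

        coords = np.vstack([coords_pep, lipid_coords, waters])
        frames.append(
            Frame(coordinates=coords, box=box, time=fi * spec.frame_spacing)
        )

    traj = TrajectoryEnsemble(
        topology=system, frames=frames,
        label=f"synthetic-{spec.model_template}-{spec.seed}",
    )
    return traj, truth


def place_at_distance(
    traj: TrajectoryEnsemble, frame_index: int, distance: float
) -> Frame:
    """Copy of a frame with the peptide COM moved to an exact perpendicular
    distance above the bilayer COM (used for planted-distance checks)."""
    system = traj.topology
    frame = traj.frames[frame_index]
    coords = frame.coordinates.copy()
    pep_idx = system.peptide_indices
    bil_idx = np.flatnonzero(system.bilayer_mask)
    m_pep = system.mass[pep_idx]
    z_pep = (coords[pep_idx, 2] * m_pep).sum() / m_pep.sum()
    m_bil = system.mass[bil_idx]
    z_bil = (coords[bil_idx, 2] * m_bil).sum() / m_bil.sum()
    coords[pep_idx, 2] += (z_bil + distance) - z_pep
    return Frame(coordinates=coords, box=frame.box.copy(), time=frame.time)


def sample_two_state_cv(
    means, sds, weights, n: int, seed: int
) -> np.ndarray:
    """Gaussian-mixture collective-variable sample (e.g. peptide-bilayer
    distance with bound and unbound modes)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(means) == len(sds) == len(weights)):
        raise MembindError("means, sds and weights must have equal length")
    if np.any(sds <= 0):
        raise MembindError("sds must be positive")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise MembindError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    modes = rng.choice(len(means), size=n, p=weights)
    return rng.normal(means[modes], sds[modes])


def two_state_delta_g(weights) -> float:
    """Analytic free-energy gap between two modes: -ln(w2 / w1) in kT."""
    w = np.asarray(weights, dtype=float)
    if len(w) != 2 or np.any(w <= 0):
        raise MembindError("need two positive weights")
    return float(-np.log(w[1] / w[0]))
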