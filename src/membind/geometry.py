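"""PBC-aware geometry: minimum-image distances, centres of mass, contacts
(cell list), insertion depths, contact maps and Kabsch RMSD.

Conventions
-----------
* Membrane normal is the z axis.
* Contact comparison is closed (``distance <= cutoff``).
* Centres of mass assume whole (unwrapped) molecules; the minimum image is
  applied only to inter-group atom-pair distances.
* Depth of a residue = |z_residue_COM - z_bilayer_COM| - half_thickness,
  signed so residues below the surface are negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, Frame, MembindError, StructuredSystem, TrajectoryEnsemble


def min_image_displacement(p, q, box) -> np.ndarray:
    """Displacement q - p under the orthorhombic minimum-image convention.

    Broadcasts over leading dimensions of ``p``/``q``.
    """
    box = np.asarray(box, dtype=float)
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p, q, box) -> float | np.ndarray:
    d = min_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def center_of_mass(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of an atom subset (assumed whole)."""
    coordinates = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coordinates.shape[0] == 0:
        raise MembindError("center of mass of an empty atom subset")
    return (coordinates * masses[:, None]).sum(axis=0) / masses.sum()


def group_com(system: StructuredSystem, frame: Frame, indices) -> np.ndarray:
    indices = np.asarray(indices)
    return center_of_mass(frame.coordinates[indices], system.mass[indices])


def peptide_bilayer_distance(system: StructuredSystem, frame: Frame) -> float:
    """Perpendicular (z) COM distance between peptide and bilayer."""
    z_pep = group_com(system, frame, system.peptide_indices)[2]
    z_bil = group_com(system, frame, np.flatnonzero(system.bilayer_mask))[2]
    return float(abs(z_pep - z_bil))


@dataclass
class DepthProfile:
    """Signed per-residue distance to the membrane surface (nm); negative
    values are buried below the surface."""

    residue_ids: np.ndarray
    depths: np.ndarray

    def by_region(self, system: StructuredSystem) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for resid, depth in zip(self.residue_ids, self.depths):
            out.setdefault(system.region_of(int(resid)), []).append(depth)
        return {k: np.array(v) for k, v in out.items()}


def residue_depths(
    system: StructuredSystem, frame: Frame, config: AnalysisConfig
) -> DepthProfile:
    z_bil = group_com(system, frame, np.flatnonzero(system.bilayer_mask))[2]
    resids = system.peptide_residues
    depths = np.empty(len(resids))
    for k, resid in enumerate(resids):
        idx = system.peptide_residue_atoms(int(resid))
        z_res = group_com(system, frame, idx)[2]
        depths[k] = abs(z_res - z_bil) - config.half_thickness
    return DepthProfile(residue_ids=resids.copy(), depths=depths)


@dataclass
class ContactResult:
    """Single-frame peptide-bilayer contact accounting."""

    n_contacts: int
    residue_ids: np.ndarray
    per_residue_contact: np.ndarray  # bool, aligned with residue_ids

    @property
    def n_contact_residues(self) -> int:
        return int(self.per_residue_contact.sum())


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return coords - box * np.floor(coords / box)


def _cell_list_pairs(
    xa: np.ndarray, xb: np.ndarray, box: np.ndarray, cutoff: float
):
    """Yield (ia, ib_array) candidate neighbours of each A atom via a
    cell list over B.  Exact: every pair within ``cutoff`` is a candidate.
    """
    box = np.asarray(box, dtype=float)
    ncell = np.maximum(np.floor(box / cutoff).astype(int), 1)
    cell_size = box / ncell
    wa = _wrap(xa, box)
    wb = _wrap(xb, box)
    cb = np.minimum((wb / cell_size).astype(int), ncell - 1)
    ca = np.minimum((wa / cell_size).astype(int), ncell - 1)

    cells: dict[tuple[int, int, int], list[int]] = {}
    for ib, c in enumerate(map(tuple, cb)):
        cells.setdefault(c, []).append(ib)
    cells_np = {c: np.array(v) for c, v in cells.items()}

    offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1)]
    )
    for ia, c in enumerate(ca):
        neigh = {tuple((c + off) % ncell) for off in offsets}
        cand = [cells_np[n] for n in neigh if n in cells_np]
        if cand:
            yield ia, np.concatenate(cand)


def count_contacts(
    system: StructuredSystem,
    frame: Frame,
    config: AnalysisConfig,
    selection_a: np.ndarray | None = None,
    selection_b: np.ndarray | None = None,
) -> ContactResult:
    """Count heavy-atom pairs (a in A, b in B) within the contact cutoff
    under the minimum image, and flag peptide residues with >= 1 pair.

    Defaults: A = peptide heavy atoms, B = bilayer heavy atoms.  The
    selections must be disjoint.  A cell list restricts candidate pairs;
    distances are evaluated with the same minimum-image kernel as the
    brute-force definition, so counts are exact.
    """
    sel_a = (
        system.peptide_heavy_indices if selection_a is None
        else np.asarray(selection_a)
    )
    sel_b = (
        system.bilayer_heavy_indices if selection_b is None
        else np.asarray(selection_b)
    )
    if np.intersect1d(sel_a, sel_b).size:
        raise MembindError("contact selections must be disjoint")
    cutoff = config.contact_cutoff
    xa = frame.coordinates[sel_a]
    xb = frame.coordinates[sel_b]

    resids = system.peptide_residues
    res_flag = {int(r): False for r in resids}
    atom_res = system.residue_index
    n_pairs = 0
    for ia, ib_arr in _cell_list_pairs(xa, xb, frame.box, cutoff):
        d = min_image_distance(xa[ia], xb[ib_arr], frame.box)
        hits = int(np.count_nonzero(d <= cutoff))
        if hits:
            n_pairs += hits
            global_ia = int(sel_a[ia])
            if system.peptide_mask[global_ia]:
                res_flag[int(atom_res[global_ia])] = True
    per_res = np.array([res_flag[int(r)] for r in resids], dtype=bool)
    return ContactResult(
        n_contacts=n_pairs, residue_ids=resids.copy(),
        per_residue_contact=per_res,
    )


def brute_force_contacts(
    system: StructuredSystem,
    frame: Frame,
    config: AnalysisConfig,
    selection_a: np.ndarray | None = None,
    selection_b: np.ndarray | None = None,
) -> int:
    """O(N^2) reference pair count (kept for cross-validation)."""
    sel_a = (
        system.peptide_heavy_indices if selection_a is None
        else np.asarray(selection_a)
    )
    sel_b = (
        system.bilayer_heavy_indices if selection_b is None
        else np.asarray(selection_b)
    )
    xa = frame.coordinates[sel_a]
    xb = frame.coordinates[sel_b]
    d = min_image_distance(xa[:, None, :], xb[None, :, :], frame.box)
    return int(np.count_nonzero(d <= config.contact_cutoff))


def contact_fractions(
    traj: TrajectoryEnsemble,
    config: AnalysisConfig,
    bound_only: bool = False,
    contacts: list[ContactResult] | None = None,
):
    """Fraction of frames in which each peptide residue touches the bilayer.

    Returns ``(residue_ids, fractions, mean_fraction)``.  With
    ``bound_only`` the denominator is restricted to frames having >= 1
    contact.  Precomputed per-frame ``ContactResult`` objects may be passed
    to avoid recomputation.
    """
    if len(traj) == 0:
        raise MembindError("contact_fractions on an empty ensemble")
    if contacts is None:
        contacts = [count_contacts(traj.topology, f, config) for f in traj.frames]
    used = [c for c in contacts if (c.n_contacts > 0 or not bound_only)]
    resids = contacts[0].residue_ids
    if not used:
        return resids.copy(), np.zeros(len(resids)), 0.0
    stack = np.stack([c.per_residue_contact for c in used])
    fractions = stack.mean(axis=0)
    return resids.copy(), fractions, float(fractions.mean())


def residue_contact_map(
    traj: TrajectoryEnsemble,
    config: AnalysisConfig,
    frame_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric per-residue intra-peptide contact probability matrix with a
    unit diagonal, averaged over the ensemble (optionally a frame subset).
    """
    system = traj.topology
    resids = system.peptide_residues
    n = len(resids)
    res_atoms = [system.peptide_residue_heavy_atoms(int(r)) for r in resids]
    atom_idx = np.concatenate(res_atoms)
    atom_res = np.concatenate(
        [np.full(len(a), k) for k, a in enumerate(res_atoms)]
    )
    frames = (
        traj.frames if frame_indices is None
        else [traj.frames[int(i)] for i in frame_indices]
    )
    if not frames:
        raise MembindError("residue_contact_map on an empty frame selection")
    acc = np.zeros((n, n))
    for frame in frames:
        x = frame.coordinates[atom_idx]
        d = min_image_distance(x[:, None, :], x[None, :, :], frame.box)
        pair = d <= config.contact_cutoff
        ind = np.zeros((n, n), dtype=bool)
        ii, jj = np.nonzero(pair)
        ind[atom_res[ii], atom_res[jj]] = True
        acc += ind
    acc /= len(frames)
    np.fill_diagonal(acc, 1.0)
    return acc


def top_longrange_pairs(
    contact_map: np.ndarray, k: int, config: AnalysisConfig
) -> list[tuple[int, int, float]]:
    """Top-k residue pairs by contact probability among pairs at least
    ``longrange_min_separation`` residues apart.  Ties break on (i, j)
    lexicographic order; returns (residue_i, residue_j, probability) with
    1-based residue numbering and i < j.
    """
    m = np.asarray(contact_map)
    if not np.allclose(m, m.T):
        raise MembindError("contact map must be symmetric")
    n = m.shape[0]
    pairs = [
        (i + 1, j + 1, float(m[i, j]))
        for i in range(n)
        for j in range(i + config.longrange_min_separation, n)
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs[:k]


def kabsch_rmsd(
    reference_coords: np.ndarray, coords: np.ndarray
) -> float:
    """Minimal RMSD over proper rigid motions (rotation det = +1 plus
    translation) superposing ``coords`` onto ``reference_coords``.
    """
    ref = np.asarray(reference_coords, dtype=float)
    mob = np.asarray(coords, dtype=float)
    if ref.shape != mob.shape:
        raise MembindError(
            f"coordinate count mismatch: {ref.shape} vs {mob.shape}"
        )
    if ref.shape[0] < 3:
        raise MembindError("kabsch_rmsd needs >= 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    sv_ref = np.linalg.svd(ref_c, compute_uv=False)
    if sv_ref[1] < 1e-9 * max(sv_ref[0], 1.0):
        raise MembindError("kabsch_rmsd: reference atoms are collinear")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.ones(3)
    d[-1] = sign  # reflection fix on the smallest singular direction
    rot = u @ np.diag(d) @ vt
    aligned = mob_c @ rot
    diff = aligned - ref_c
    return float(np.sqrt((diff * diff).sum() / ref.shape[0]))


def peptide_rmsd_series(
    traj: TrajectoryEnsemble, reference: np.ndarray | None = None
) -> np.ndarray:
    """Heavy-atom peptide RMSD of every frame against a reference
    conformation (default: frame 0)."""
    idx = traj.topology.peptide_heavy_indices
    if reference is None:
        reference = traj.frames[0].coordinates[idx]
    return np.array(
        [kabsch_rmsd(reference, f.coordinates[idx]) for f in traj.frames]
    )
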