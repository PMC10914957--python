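"""Free-energy landscapes, basins, microstates and the binding-model
classifier.

Free energies are natively in kT units: G = -ln P, shifted so the occupied
minimum is 0; empty bins are masked (NaN).  Conversion to kcal/mol uses
``kB * temperature`` from the analysis config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AnalysisConfig, Frame, MembindError, StructuredSystem, TrajectoryEnsemble
from . import geometry, secstruct

MODEL_LABELS = (
    "model1", "model2", "model3", "model4", "unclassified", "unbound"
)


def _edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


@dataclass
class FelGrid:
    """Binned probability and free energy over one or two collective
    variables.  ``G`` is in kT, NaN on unoccupied bins, min-shifted to 0."""

    axis_names: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    P: np.ndarray
    G: np.ndarray
    sample_bins: np.ndarray | None = None  # per-sample bin index, (n, ndim)

    @property
    def occupied(self) -> np.ndarray:
        return self.P > 0

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def free_energy(self, units: str = "kT", config: AnalysisConfig | None = None) -> np.ndarray:
        if units == "kT":
            return self.G
        if units == "kcal/mol":
            cfg = config or AnalysisConfig()
            return self.G * cfg.kT
        raise MembindError(f"unknown free-energy units {units!r}")


def _grid_from_counts(axis_names, edges, counts, sample_bins):
    total = counts.sum()
    if total == 0:
        raise MembindError("free-energy grid built from zero samples")
    P = counts / total
    with np.errstate(divide="ignore"):
        G = -np.log(np.where(P > 0, P, np.nan))
    G = G - np.nanmin(G)
    return FelGrid(
        axis_names=tuple(axis_names),
        edges=tuple(edges),
        P=P,
        G=G,
        sample_bins=sample_bins,
    )


def compute_fel_2d(
    x_values,
    y_values,
    config: AnalysisConfig,
    bin_width_x: float | None = None,
    bin_width_y: float | None = None,
    axis_names: tuple[str, str] = ("distance", "contacts"),
) -> FelGrid:
    """2D free-energy surface over two equal-length value series.

    Default bin widths are the configured distance/contacts widths; pass
    explicit widths for other variable pairs.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise MembindError("x and y series must have equal length")
    wx = bin_width_x if bin_width_x is not None else config.fel_bins_distance
    wy = bin_width_y if bin_width_y is not None else config.fel_bins_contacts
    ex = _edges(x, wx)
    ey = _edges(y, wy)
    ix = np.clip(np.searchsorted(ex, x, side="right") - 1, 0, len(ex) - 2)
    iy = np.clip(np.searchsorted(ey, y, side="right") - 1, 0, len(ey) - 2)
    counts = np.zeros((len(ex) - 1, len(ey) - 1))
    np.add.at(counts, (ix, iy), 1.0)
    return _grid_from_counts(
        axis_names, (ex, ey), counts, np.column_stack([ix, iy])
    )


@dataclass
class Fel1D:
    axis_name: str
    edges: np.ndarray
    P: np.ndarray
    G: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def minima(self) -> np.ndarray:
        """Bin centers of local minima of G on the occupied support."""
        g = np.where(np.isnan(self.G), np.inf, self.G)
        mins = []
        for i in range(len(g)):
            if np.isinf(g[i]):
                continue
            left = g[i - 1] if i > 0 else np.inf
            right = g[i + 1] if i < len(g) - 1 else np.inf
            if g[i] <= left and g[i] <= right and (g[i] < left or g[i] < right):
                mins.append(i)
            elif g[i] <= left and g[i] <= right and np.isinf(left) and np.isinf(right):
                mins.append(i)
        return self.centers[np.array(mins, dtype=int)] if mins else np.array([])


def project_fel_1d(grid_or_values, axis=0, config: AnalysisConfig | None = None,
                   bin_width: float | None = None,
                   axis_name: str = "distance") -> Fel1D:
    """Marginalise a 2D grid onto one axis (or histogram a raw series) and
    convert to a min-shifted free-energy profile."""
    if isinstance(grid_or_values, FelGrid):
        grid = grid_or_values
        if isinstance(axis, str):
            axis = grid.axis_names.index(axis)
        P = grid.P.sum(axis=1 - axis)
        name = grid.axis_names[axis]
        edges = grid.edges[axis]
    else:
        values = np.asarray(grid_or_values, dtype=float)
        cfg = config or AnalysisConfig()
        width = bin_width if bin_width is not None else cfg.fel_bins_distance
        edges = _edges(values, width)
        counts, _ = np.histogram(values, bins=edges)
        P = counts / counts.sum()
        name = axis_name
    with np.errstate(divide="ignore"):
        G = -np.log(np.where(P > 0, P, np.nan))
    G = G - np.nanmin(G)
    return Fel1D(axis_name=name, edges=edges, P=P, G=G)


@dataclass
class Basin:
    label: str
    min_index: tuple[int, int]
    min_coords: tuple[float, float]
    G_min: float
    member_frames: np.ndarray
    member_bins: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class BasinSet:
    basins: list[Basin]
    grid: FelGrid

    def __len__(self) -> int:
        return len(self.basins)

    def frame_labels(self, n_frames: int) -> np.ndarray:
        labels = np.full(n_frames, "", dtype=object)
        for b in self.basins:
            labels[b.member_frames] = b.label
        return labels


_NEIGHBORS = [
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
]


def _local_minima(G: np.ndarray) -> list[tuple[int, int]]:
    g = np.where(np.isnan(G), np.inf, G)
    nx, ny = g.shape
    mins = []
    for i in range(nx):
        for j in range(ny):
            if np.isinf(g[i, j]):
                continue
            best = True
            for di, dj in _NEIGHBORS:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny:
                    if g[a, b] < g[i, j] or (
                        g[a, b] == g[i, j] and (a, b) < (i, j)
                    ):
                        best = False
                        break
            if best:
                mins.append((i, j))
    return mins


def _descend(G: np.ndarray, start: tuple[int, int]) -> tuple[int, int]:
    g = np.where(np.isnan(G), np.inf, G)
    nx, ny = g.shape
    i, j = start
    while True:
        best, best_g = None, g[i, j]
        for di, dj in _NEIGHBORS:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and not np.isinf(g[a, b]):
                if g[a, b] < best_g or (
                    g[a, b] == best_g and best is None and (a, b) < (i, j)
                ):
                    best, best_g = (a, b), g[a, b]
        if best is None:
            return (i, j)
        i, j = best


def find_basins(
    grid: FelGrid,
    config: AnalysisConfig | None = None,
    min_depth_kT: float | None = None,
    min_separation_bins: int | None = None,
) -> BasinSet:
    """Detect basins of a 2D free-energy grid.

    Local minima on the occupied grid (8-neighbourhood) are kept when their
    G lies below ``global_min + min_depth_kT`` and they are pairwise
    separated by at least ``min_separation_bins`` (Chebyshev metric; the
    shallower of a close pair is dropped).  Every occupied bin is assigned
    to a surviving basin by steepest descent; basins swallowed by the
    filters hand their catchment to the nearest survivor.  Labels a, b, c..
    order basins by descending first-axis coordinate, then ascending G.
    """
    cfg = config or AnalysisConfig()
    depth = min_depth_kT if min_depth_kT is not None else cfg.basin_min_depth_kT
    sep = (
        min_separation_bins if min_separation_bins is not None
        else cfg.basin_min_separation_bins
    )
    minima = _local_minima(grid.G)
    if not minima:
        raise MembindError("no occupied bins in the grid")
    g_at = {m: float(grid.G[m]) for m in minima}
    g_global = min(g_at.values())
    kept = [m for m in minima if g_at[m] <= g_global + depth]
    kept.sort(key=lambda m: (g_at[m], m))
    surviving: list[tuple[int, int]] = []
    for m in kept:
        if all(
            max(abs(m[0] - s[0]), abs(m[1] - s[1])) >= sep for s in surviving
        ):
            surviving.append(m)

    # steepest-descent catchment for every occupied bin
    catchment: dict[tuple[int, int], tuple[int, int]] = {}
    occupied = list(zip(*np.nonzero(grid.occupied)))
    for cell in occupied:
        term = _descend(grid.G, cell)
        if term not in surviving:
            term = min(
                surviving,
                key=lambda s: (
                    (s[0] - term[0]) ** 2 + (s[1] - term[1]) ** 2,
                    s,
                ),
            )
        catchment[cell] = term

    order = sorted(
        surviving,
        key=lambda m: (-grid.centers(0)[m[0]], grid.G[m]),
    )
    labels = {m: chr(ord("a") + k) for k, m in enumerate(order)}

    basins = []
    for m in order:
        bins = [c for c, t in catchment.items() if t == m]
        if grid.sample_bins is not None:
            bin_set = set(bins)
            members = np.array(
                [
                    k for k, sb in enumerate(map(tuple, grid.sample_bins))
                    if sb in bin_set
                ],
                dtype=int,
            )
        else:
            members = np.array([], dtype=int)
        basins.append(
            Basin(
                label=labels[m],
                min_index=m,
                min_coords=(
                    float(grid.centers(0)[m[0]]),
                    float(grid.centers(1)[m[1]]),
                ),
                G_min=float(grid.G[m]),
                member_frames=members,
                member_bins=bins,
            )
        )
    return BasinSet(basins=basins, grid=grid)


@dataclass
class Microstate:
    label: str
    group: int  # 1 = high-beta, 2 = low-beta
    mean_beta: float
    member_frames: np.ndarray
    G_min: float


def per_basin_fel(
    rmsd_values: np.ndarray,
    beta_values: np.ndarray,
    basin: Basin,
    config: AnalysisConfig,
) -> tuple[FelGrid, list[Microstate]]:
    """FEL over (RMSD, beta content) restricted to a basin's member frames,
    and its microstates grouped by the beta threshold ('x1' high-beta, 'x2'
    low-beta, for basin label x)."""
    members = basin.member_frames
    if len(members) == 0:
        raise MembindError(f"basin {basin.label} has no member frames")
    if len(members) < 10:
        warnings.warn(
            f"basin {basin.label} has only {len(members)} member frames",
            stacklevel=2,
        )
    r = np.asarray(rmsd_values, dtype=float)[members]
    b = np.asarray(beta_values, dtype=float)[members]
    grid = compute_fel_2d(
        r, b, config,
        bin_width_x=config.fel_bins_rmsd,
        bin_width_y=config.fel_bins_beta,
        axis_names=("rmsd", "beta"),
    )
    subbasins = find_basins(grid, config)
    microstates = []
    counters = {1: 0, 2: 0}
    for sub in subbasins.basins:
        sub_members = members[sub.member_frames]
        mean_beta = float(b[sub.member_frames].mean())
        group = 1 if mean_beta >= config.microstate_beta_threshold else 2
        counters[group] += 1
        suffix = str(group) if counters[group] == 1 else f"{group}.{counters[group]}"
        microstates.append(
            Microstate(
                label=f"{basin.label}{suffix}",
                group=group,
                mean_beta=mean_beta,
                member_frames=sub_members,
                G_min=sub.G_min,
            )
        )
    return grid, microstates


def partition_bound(traj_or_counts, config: AnalysisConfig | None = None) -> np.ndarray:
    """Per-frame bound flag: bound iff the frame has > 0 peptide-bilayer
    contacts.  Accepts either an ensemble (contacts computed here) or a
    precomputed array of per-frame contact counts."""
    if isinstance(traj_or_counts, TrajectoryEnsemble):
        cfg = config or AnalysisConfig()
        counts = np.array(
            [
                geometry.count_contacts(traj_or_counts.topology, f, cfg).n_contacts
                for f in traj_or_counts.frames
            ]
        )
    else:
        counts = np.asarray(traj_or_counts)
    return counts > 0


@dataclass
class FrameFeatures:
    """Inputs to the binding-model classifier, all produced by the geometry
    and secondary-structure stages."""

    distance: float
    n_contacts: int
    n_contact_residues: int
    beta_fraction: float
    helix_fraction_total: float
    helix_fraction_by_region: dict[str, float]
    buried_fraction_by_region: dict[str, float]
    min_depth: float


def extract_features(
    system: StructuredSystem,
    frame: Frame,
    config: AnalysisConfig,
    ss: np.ndarray | None = None,
    contact: "geometry.ContactResult | None" = None,
) -> FrameFeatures:
    if contact is None:
        contact = geometry.count_contacts(system, frame, config)
    if ss is None:
        ss = secstruct.assign_secstruct(system, frame)
    depth = geometry.residue_depths(system, frame, config)
    regions = config.regions.labels
    helix_by_region: dict[str, float] = {}
    buried_by_region: dict[str, float] = {}
    resids = depth.residue_ids
    region_of = np.array([system.region_of(int(r)) for r in resids])
    is_helix = np.isin(ss, ("G", "H", "I"))
    for label in regions:
        mask = region_of == label
        helix_by_region[label] = float(is_helix[mask].mean()) if mask.any() else 0.0
        buried_by_region[label] = (
            float((depth.depths[mask] < 0).mean()) if mask.any() else 0.0
        )
    return FrameFeatures(
        distance=geometry.peptide_bilayer_distance(system, frame),
        n_contacts=contact.n_contacts,
        n_contact_residues=contact.n_contact_residues,
        beta_fraction=secstruct.beta_content(ss),
        helix_fraction_total=float(is_helix.mean()),
        helix_fraction_by_region=helix_by_region,
        buried_fraction_by_region=buried_by_region,
        min_depth=float(depth.depths.min()),
    )


def classify_binding_model(
    features: FrameFeatures, config: AnalysisConfig | None = None
) -> str:
    """First-match rule cascade over per-frame features.

    unbound: no contacts.
    model4: CHC and CT majority-buried, coil-dominated (beta and helix
            both below 10%).
    model3: CT majority-buried with 10-30% beta content.
    model1: 30-50% beta, burial confined to CT, 2-15 contacting residues.
    model2: helical N-terminus (>= 20%), surface-lying (no residue below
            -0.2 nm), 2-15 contacting residues.
    otherwise unclassified.
    """
    cfg = config or AnalysisConfig()
    f = features
    if f.n_contacts == 0:
        return "unbound"
    buried = f.buried_fraction_by_region
    helix_total = f.helix_fraction_total
    beta = f.beta_fraction
    n_res = f.n_contact_residues
    in_contact_band = (
        cfg.classifier_min_contact_residues
        <= n_res
        <= cfg.classifier_max_contact_residues
    )
    if (
        buried.get("CHC", 0.0) >= cfg.classifier_buried_fraction
        and buried.get("CT", 0.0) >= cfg.classifier_buried_fraction
        and beta < cfg.classifier_beta_low
        and helix_total < cfg.classifier_beta_low
    ):
        return "model4"
    if (
        buried.get("CT", 0.0) >= cfg.classifier_buried_fraction
        and cfg.classifier_beta_low <= beta < cfg.classifier_beta_mid
    ):
        return "model3"
    only_ct_buried = all(
        v == 0.0 for k, v in buried.items() if k != "CT"
    )
    if (
        cfg.classifier_beta_mid <= beta <= cfg.classifier_beta_high
        and only_ct_buried
        and in_contact_band
    ):
        return "model1"
    if (
        f.helix_fraction_by_region.get("NT", 0.0) >= cfg.classifier_helix_nt
        and f.min_depth > cfg.classifier_surface_depth
        and in_contact_band
    ):
        return "model2"
    return "unclassified"


def basin_relative_free_energy(
    basin_populations, config: AnalysisConfig | None = None
) -> np.ndarray:
    """Relative stability of basins/microstates from their populations:
    dG_i = -kT ln(P_i / P_max) in kT units, 0 at the most populated;
    zero-population entries come back as +inf (rendered NA by the table
    writer)."""
    pops = np.asarray(basin_populations, dtype=float)
    if np.any(pops < 0) or pops.sum() == 0:
        raise MembindError("populations must be non-negative and not all zero")
    pmax = pops.max()
    with np.errstate(divide="ignore"):
        return np.where(pops > 0, -np.log(pops / pmax), np.inf)
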