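"""Shared domain types: topology, frames, regions and the analysis config.

Lengths are nanometres everywhere inside the package; file readers convert
at the boundary.  Boxes are orthorhombic (edge lengths only) -- triclinic
input is rejected by the readers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import chem

GROUPS = ("peptide", "lipid_POPC", "lipid_POPS", "lipid_CHOL", "water", "ion")
LIPID_GROUPS = ("lipid_POPC", "lipid_POPS", "lipid_CHOL")
REGION_LABELS = ("NT", "CHC", "CL", "CT")


class MembindError(Exception):
    """Base class for package errors."""


class ConfigurationError(MembindError):
    pass


class TopologyError(MembindError):
    pass


class FileFormatError(MembindError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the structured system.

    ``group`` may be left as ``None`` to have :func:`build_system` infer it
    from the residue name.
    """

    serial: int
    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    group: str | None = None

    @property
    def element_class(self) -> str:
        return "hydrogen" if self.element == "H" else "heavy"

    def __post_init__(self):
        if self.serial < 1:
            raise TopologyError(f"atom serial must be >= 1, got {self.serial}")
        if self.mass <= 0:
            raise TopologyError(
                f"atom {self.serial} ({self.name}) has non-positive mass"
            )
        if self.residue_index < 1:
            raise TopologyError(
                f"atom {self.serial} has residue index {self.residue_index} < 1"
            )
        if self.group is not None and self.group not in GROUPS:
            raise TopologyError(
                f"unknown group {self.group!r} for atom {self.serial}"
            )


@dataclass(frozen=True)
class RegionMap:
    """Contiguous partition of the peptide residue range into labelled
    regions (N-terminus, central hydrophobic core, central loop, C-terminus).
    """

    regions: tuple[tuple[str, int, int], ...] = (
        ("NT", 1, 16),
        ("CHC", 17, 21),
        ("CL", 22, 29),
        ("CT", 30, 40),
    )

    def __post_init__(self):
        prev_last = None
        for label, first, last in self.regions:
            if first > last:
                raise ConfigurationError(
                    f"region {label}: first residue {first} > last {last}"
                )
            if prev_last is not None and first != prev_last + 1:
                raise ConfigurationError(
                    f"regions must be contiguous; {label} starts at {first}, "
                    f"previous region ended at {prev_last}"
                )
            prev_last = last

    @property
    def first_residue(self) -> int:
        return self.regions[0][1]

    @property
    def last_residue(self) -> int:
        return self.regions[-1][2]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.regions)

    def region_of(self, residue_index: int) -> str:
        for label, first, last in self.regions:
            if first <= residue_index <= last:
                return label
        raise ConfigurationError(
            f"residue {residue_index} is outside the region map "
            f"({self.first_residue}..{self.last_residue})"
        )

    def residues_of(self, label: str) -> range:
        for lab, first, last in self.regions:
            if lab == label:
                return range(first, last + 1)
        raise ConfigurationError(f"unknown region label {label!r}")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RegionMap":
        regions = tuple(
            (str(label), int(pair[0]), int(pair[1]))
            for label, pair in mapping.items()
        )
        return cls(regions=tuple(sorted(regions, key=lambda r: r[1])))

    def to_dict(self) -> dict:
        return {label: [first, last] for label, first, last in self.regions}


class StructuredSystem:
    """Topology with per-atom group labels and per-residue region labels.

    Backed by flat numpy arrays; index sets used throughout the analysis
    stack (peptide heavy atoms, bilayer heavy atoms, per-residue slices)
    are computed once at construction time.
    """

    def __init__(self, records: Sequence[AtomRecord], region_map: RegionMap):
        if not records:
            raise TopologyError("cannot build a system from zero atoms")
        serials = np.array([r.serial for r in records], dtype=int)
        if len(np.unique(serials)) != len(serials):
            raise TopologyError("atom serials are not unique")

        groups = []
        for r in records:
            if r.group is not None:
                groups.append(r.group)
            else:
                try:
                    groups.append(chem.infer_group(r.residue_name))
                except KeyError as exc:
                    raise TopologyError(str(exc)) from None

        self.records = tuple(records)
        self.region_map = region_map
        self.serial = serials
        self.name = np.array([r.name for r in records], dtype=object)
        self.element = np.array([r.element for r in records], dtype=object)
        self.mass = np.array([r.mass for r in records], dtype=float)
        self.residue_index = np.array(
            [r.residue_index for r in records], dtype=int
        )
        self.residue_name = np.array(
            [r.residue_name for r in records], dtype=object
        )
        self.group = np.array(groups, dtype=object)
        self.is_hydrogen = np.array(
            [r.element == "H" for r in records], dtype=bool
        )

        self.n_atoms = len(records)
        pept = self.group == "peptide"
        self.peptide_mask = pept
        self.peptide_residues = np.unique(self.residue_index[pept])
        for resid in self.peptide_residues:
            # raises ConfigurationError if a peptide residue lies outside map
            region_map.region_of(int(resid))
        self.peptide_region = {
            int(resid): region_map.region_of(int(resid))
            for resid in self.peptide_residues
        }
        bilayer = np.isin(self.group, LIPID_GROUPS)
        self.bilayer_mask = bilayer
        heavy = ~self.is_hydrogen
        self.heavy_mask = heavy
        self.peptide_heavy_indices = np.flatnonzero(pept & heavy)
        self.bilayer_heavy_indices = np.flatnonzero(bilayer & heavy)
        self.peptide_indices = np.flatnonzero(pept)

        self._residue_atoms: dict[int, np.ndarray] = {}
        self._residue_heavy: dict[int, np.ndarray] = {}
        for resid in self.peptide_residues:
            in_res = pept & (self.residue_index == resid)
            self._residue_atoms[int(resid)] = np.flatnonzero(in_res)
            self._residue_heavy[int(resid)] = np.flatnonzero(in_res & heavy)

    def group_indices(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise TopologyError(f"unknown group {group!r}")
        return np.flatnonzero(self.group == group)

    def peptide_residue_atoms(self, residue_index: int) -> np.ndarray:
        try:
            return self._residue_atoms[int(residue_index)]
        except KeyError:
            raise TopologyError(
                f"residue {residue_index} is not a peptide residue"
            ) from None

    def peptide_residue_heavy_atoms(self, residue_index: int) -> np.ndarray:
        try:
            return self._residue_heavy[int(residue_index)]
        except KeyError:
            raise TopologyError(
                f"residue {residue_index} is not a peptide residue"
            ) from None

    def region_of(self, residue_index: int) -> str:
        if int(residue_index) not in self.peptide_region:
            raise ConfigurationError(
                f"residue {residue_index} is not a peptide residue with a region"
            )
        return self.peptide_region[int(residue_index)]

    def peptide_atom_index(self, residue_index: int, name: str) -> int:
        idx = self.peptide_residue_atoms(residue_index)
        hits = idx[self.name[idx] == name]
        if len(hits) == 0:
            raise TopologyError(
                f"residue {residue_index} has no atom named {name!r}"
            )
        return int(hits[0])


def build_system(
    atom_records: Sequence[AtomRecord],
    region_map: RegionMap | None = None,
) -> StructuredSystem:
    """Assemble a :class:`StructuredSystem`, inferring missing group labels
    from residue names.  Raises :class:`TopologyError` for unknown residue
    names and :class:`ConfigurationError` for peptide residues outside the
    region map.
    """
    return StructuredSystem(atom_records, region_map or RegionMap())


@dataclass
class Frame:
    """Coordinates (nm) plus orthorhombic box edge lengths (nm) at a time
    point (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise MembindError("frame coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise MembindError("frame box must be three orthorhombic edge lengths")
        if np.any(self.box <= 0):
            raise MembindError("box edge lengths must be positive")
        if self.time < 0:
            raise MembindError("frame time must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class TrajectoryEnsemble:
    topology: StructuredSystem
    frames: list[Frame]
    label: str = ""

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise MembindError("frame times must be non-decreasing")
        for i, f in enumerate(self.frames):
            if f.n_atoms != self.topology.n_atoms:
                raise MembindError(
                    f"frame {i} has {f.n_atoms} atoms, topology has "
                    f"{self.topology.n_atoms}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)


def filter_time_window(
    traj: TrajectoryEnsemble, t_min: float, t_max: float
) -> TrajectoryEnsemble:
    """Keep frames with ``t_min <= time <= t_max`` (both bounds inclusive),
    preserving order.  An empty result is returned with a warning so callers
    can decide how to fail.
    """
    if t_min > t_max:
        raise MembindError(f"t_min ({t_min}) > t_max ({t_max})")
    kept = [f for f in traj.frames if t_min <= f.time <= t_max]
    if not kept:
        warnings.warn(
            f"time window [{t_min}, {t_max}] ns selects no frames "
            f"from ensemble {traj.label!r}",
            stacklevel=2,
        )
    return TrajectoryEnsemble(topology=traj.topology, frames=kept,
                              label=traj.label)


@dataclass(frozen=True)
class AnalysisConfig:
    """Every numeric criterion of the analysis in one place.

    Distances in nm, angles in degrees, times in ns, temperature in K.
    ``kB`` is in kcal/(mol*K); free energies are handled natively in kT and
    converted with ``kB * temperature`` on request.
    """

    contact_cutoff: float = 0.5
    hbond_da_cutoff: float = 0.3
    hbond_angle_cutoff: float = 20.0
    half_thickness: float = 2.0
    temperature: float = 343.0
    kB: float = 0.0019872
    fel_bins_distance: float = 0.05
    fel_bins_contacts: float = 10.0
    fel_bins_rmsd: float = 0.05
    fel_bins_beta: float = 0.025
    equilibration_discard: float = 200.0
    longrange_min_separation: int = 3
    frame_spacing: float = 1.0

    # H-bond conventions (see module docs): "donor" = angle(D->H, D->A),
    # "linear" = angle D-H...A at the hydrogen with cutoff 180-deg - given.
    hbond_angle_convention: str = "donor"
    met_sulfur_acceptor: bool = False

    # Basin / microstate extraction.
    basin_min_depth_kT: float = 1.0
    basin_min_separation_bins: int = 2
    microstate_beta_threshold: float = 0.20

    # Binding-model classifier thresholds.
    classifier_buried_fraction: float = 0.5
    classifier_beta_low: float = 0.10
    classifier_beta_mid: float = 0.30
    classifier_beta_high: float = 0.50
    classifier_helix_nt: float = 0.20
    classifier_surface_depth: float = -0.2
    classifier_min_contact_residues: int = 2
    classifier_max_contact_residues: int = 15

    regions: RegionMap = field(default_factory=RegionMap)

    def __post_init__(self):
        for name in ("contact_cutoff", "hbond_da_cutoff", "half_thickness",
                     "fel_bins_distance", "fel_bins_contacts",
                     "fel_bins_rmsd", "fel_bins_beta", "frame_spacing"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 < self.hbond_angle_cutoff < 180:
            raise ConfigurationError("hbond_angle_cutoff must be in (0, 180)")
        if self.equilibration_discard < 0:
            raise ConfigurationError("equilibration_discard must be >= 0")
        if self.temperature <= 0 or self.kB <= 0:
            raise ConfigurationError("temperature and kB must be > 0")
        if self.hbond_angle_convention not in ("donor", "linear"):
            raise ConfigurationError(
                "hbond_angle_convention must be 'donor' or 'linear'"
            )

    @property
    def kT(self) -> float:
        """Thermal energy in kcal/mol at the configured temperature."""
        return self.kB * self.temperature

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        if "regions" in data and not isinstance(data["regions"], RegionMap):
            data["regions"] = RegionMap.from_dict(data["regions"])
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = value.to_dict() if isinstance(value, RegionMap) else value
        return out

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
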