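"""Coarse pseudo-lipid bilayer slab on jittered lattices.

Each lipid is a handful of sites: a headgroup cluster at the surface
(|z - center| = half_thickness) and tail carbons filling the slab.  This is
enough structure for every analysis stage (contacts, depths, COM, H-bond
acceptors/donors) at a tiny atom count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import chem
from ..core import AtomRecord, MembindError

# per-species site templates: (name, element, dz from surface toward center)
_LIPID_SITES = {
    "POPC": [
        ("P", "P", 0.0),
        ("O13", "O", 0.02),
        ("O14", "O", 0.02),
        ("C2", "C", 0.45),
        ("C3", "C", 0.95),
        ("C4", "C", 1.45),
    ],
    "POPS": [
        ("P", "P", 0.0),
        ("O13", "O", 0.02),
        ("O14", "O", 0.02),
        ("N", "N", -0.10),
        ("HN", "H", -0.17),
        ("C2", "C", 0.45),
        ("C3", "C", 0.95),
        ("C4", "C", 1.45),
    ],
    "CHOL": [
        ("O3", "O", 0.0),
        ("HO3", "H", -0.08),
        ("C1", "C", 0.45),
        ("C2", "C", 0.95),
        ("C3", "C", 1.45),
    ],
}
# lateral offsets for the first three (head) sites, nm
_HEAD_XY = [(0.0, 0.0), (0.18, 0.0), (0.0, 0.18)]


@dataclass
class BuiltBilayer:
    records: list[AtomRecord]
    coordinates: np.ndarray
    box_xy: tuple[float, float]
    center_z: float
    half_thickness: float

    @property
    def surface_z(self) -> tuple[float, float]:
        return (
            self.center_z - self.half_thickness,
            self.center_z + self.half_thickness,
        )


def build_bilayer(
    per_leaflet_counts: tuple[int, int, int] = (54, 18, 18),
    seed: int | None = None,
    spacing: float = 0.72,
    half_thickness: float = 2.0,
    center_z: float = 5.0,
    jitter: float = 0.04,
    start_serial: int = 1,
    start_residue: int = 1,
) -> BuiltBilayer:
    """Two leaflets of POPC/POPS/CHOL pseudo-lipids on a jittered lattice.

    ``per_leaflet_counts`` is (POPC, POPS, CHOL) per leaflet (default
    54/18/18, i.e. totals 108/36/36, composition 3:1:1).  Raises if the
    lattice cannot host the requested number of lipids.
    """
    rng = np.random.default_rng(seed)
    n_per_leaflet = int(sum(per_leaflet_counts))
    if n_per_leaflet < 1:
        raise MembindError("need at least one lipid per leaflet")
    nx = int(np.ceil(np.sqrt(n_per_leaflet)))
    ny = int(np.ceil(n_per_leaflet / nx))
    if nx * ny < n_per_leaflet:
        raise MembindError("lattice too small for the requested lipid count")
    box_x = nx * spacing
    box_y = ny * spacing

    species = (
        ["POPC"] * per_leaflet_counts[0]
        + ["POPS"] * per_leaflet_counts[1]
        + ["CHOL"] * per_leaflet_counts[2]
    )

    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = start_serial
    resid = start_residue
    for leaflet_sign in (+1, -1):
        order = rng.permutation(n_per_leaflet)
        for k in range(n_per_leaflet):
            name = species[order[k]]
            gx, gy = k % nx, k // nx
            x0 = (gx + 0.5) * spacing + rng.normal(0.0, jitter)
            y0 = (gy + 0.5) * spacing + rng.normal(0.0, jitter)
            surface = center_z + leaflet_sign * half_thickness
            for site_idx, (atom, element, dz) in enumerate(_LIPID_SITES[name]):
                if site_idx < len(_HEAD_XY) and element != "C":
                    ox, oy = _HEAD_XY[site_idx]
                else:
                    ox = rng.normal(0.0, jitter)
                    oy = rng.normal(0.0, jitter)
                z = surface - leaflet_sign * dz
                records.append(
                    AtomRecord(
                        serial=serial,
                        name=atom,
                        element=element,
                        mass=chem.ELEMENT_MASS[element],
                        residue_index=resid,
                        residue_name=name,
                        group=chem.LIPID_RESNAME_TO_GROUP[name],
                    )
                )
                coords.append(np.array([x0 + ox, y0 + oy, z]))
                serial += 1
            resid += 1
    return BuiltBilayer(
        records=records,
        coordinates=np.array(coords),
        box_xy=(box_x, box_y),
        center_z=center_z,
        half_thickness=half_thickness,
    )
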