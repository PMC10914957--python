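import numpy as np
import pytest

from membind.core import AnalysisConfig, AtomRecord, Frame, RegionMap, build_system


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def big_box():
    return np.array([50.0, 50.0, 50.0])


def make_point_system(positions, groups=None, residues=None, elements=None,
                      names=None):
    """Small helper: a system of free-standing atoms at given positions.

    Defaults: all heavy carbons, group peptide residue 1 (ALA).
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    groups = groups or ["peptide"] * n
    residues = residues or [1] * n
    elements = elements or ["C"] * n
    names = names or [f"C{i}" for i in range(n)]
    resname_for = {
        "peptide": "ALA",
        "lipid_POPC": "POPC",
        "lipid_POPS": "POPS",
        "lipid_CHOL": "CHOL",
        "water": "TIP3",
        "ion": "NA",
    }
    records = [
        AtomRecord(
            serial=i + 1,
            name=names[i],
            element=elements[i],
            mass=1.008 if elements[i] == "H" else 12.011,
            residue_index=residues[i],
            residue_name=resname_for[groups[i]],
            group=groups[i],
        )
        for i in range(n)
    ]
    return build_system(records)


@pytest.fixture
def point_system_factory():
    return make_point_system
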