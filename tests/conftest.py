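import numpy as np
import pytest

from ebdiff import (
    build_surface,
    diff_tables,
    make_mock_breakdown,
    make_toy_structure,
    parse_breakdown,
)
from ebdiff.fixtures import FixturePlan


# the canonical planted plan used across modules: known category counts,
# a fixed seed, defaults everywhere else
PLANTED_COUNTS = {"A": 12, "B": 8, "C": 5, "D": 5, "E": 7, "F": 9}


@pytest.fixture(scope="session")
def mock():
    plan = FixturePlan(category_counts=dict(PLANTED_COUNTS), seed=7)
    return make_mock_breakdown(plan)


@pytest.fixture(scope="session")
def tables(mock):
    ref = parse_breakdown(mock.ref_text, source_label="ref")
    mut = parse_breakdown(mock.mut_text, source_label="mut")
    return ref, mut


@pytest.fixture(scope="session")
def diff(mock, tables):
    ref, mut = tables
    return diff_tables(ref, mut, mock.mutations)


@pytest.fixture(scope="session")
def ball():
    """60-residue layered atom ball with its 960-sample surface cloud."""
    structure, pdb_text = make_toy_structure(60, "ball", seed=1)
    cloud = build_surface(structure)
    return structure, cloud, pdb_text


def residue_centers(structure) -> np.ndarray:
    return np.array(
        [
            np.mean([[a.x, a.y, a.z] for a in r.heavy_atoms], axis=0)
            for r in structure.residues
        ]
    )
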