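import math

import numpy as np
import pandas as pd
import pytest
import trimesh

from panelfish import CqPanel, MirnaAnnotation, NucleusGeometry
from panelfish.mirnome import DeltaCqMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(cq: np.ndarray, n_case: int, n_control: int,
               mirna_ids=None, sample_ids=None) -> CqPanel:
    """Tiny grouped panel from a raw matrix (NaN = undetected)."""
    cq = np.asarray(cq, float)
    n_m, n_s = cq.shape
    assert n_s == n_case + n_control
    mirna_ids = mirna_ids or [f"miR-{i + 1:03d}" for i in range(n_m)]
    sample_ids = sample_ids or (
        [f"case-{i + 1}" for i in range(n_case)]
        + [f"ctrl-{i + 1}" for i in range(n_control)]
    )
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=sample_ids)
    return CqPanel(
        pd.DataFrame(cq, index=mirna_ids, columns=sample_ids),
        groups,
        pd.Series("", index=sample_ids, dtype=object),
    )


def make_delta(values: np.ndarray, n_case: int, n_control: int,
               mirna_ids=None) -> DeltaCqMatrix:
    """DeltaCqMatrix straight from a value matrix, bypassing normalization."""
    values = np.asarray(values, float)
    n_m, n_s = values.shape
    mirna_ids = mirna_ids or [f"miR-{i + 1:03d}" for i in range(n_m)]
    sample_ids = (
        [f"case-{i + 1}" for i in range(n_case)]
        + [f"ctrl-{i + 1}" for i in range(n_control)]
    )
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=sample_ids)
    return DeltaCqMatrix(
        pd.DataFrame(values, index=mirna_ids, columns=sample_ids),
        list(mirna_ids),
        groups,
    )


def make_annotation(mirna_ids, cluster_members, cluster_id="clusterA") -> MirnaAnnotation:
    rows = []
    for i, mid in enumerate(mirna_ids):
        in_cluster = mid in set(cluster_members)
        rows.append((
            "chr14" if in_cluster else "chr1",
            1000 * (i + 1),
            1000 * (i + 1) + 80,
            mid,
            "14q32.31" if in_cluster else ".",
            cluster_id if in_cluster else ".",
        ))
    return MirnaAnnotation(pd.DataFrame(rows, columns=MirnaAnnotation.COLUMNS))


@pytest.fixture
def sphere_nucleus():
    return NucleusGeometry.from_ellipsoid("sphere", [0.0, 0.0, 0.0], [5.0, 5.0, 5.0])


@pytest.fixture
def ellipsoid_nucleus():
    return NucleusGeometry.from_ellipsoid("ellipsoid", [0.0, 0.0, 0.0], [6.0, 4.0, 2.0])


def bumpy_mesh(radius: float = 5.0, amplitude: float = 0.8,
               subdivisions: int = 3) -> trimesh.Trimesh:
    """Watertight, star-shaped but clearly non-ellipsoidal surface: a sphere
    with a smooth angular radius modulation."""
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = base.vertices
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    r = radius + amplitude * np.sin(2 * theta) * np.cos(3 * phi)
    return trimesh.Trimesh(vertices=v * r[:, None], faces=base.faces, process=False)


@pytest.fixture(scope="session")
def bumpy_nucleus():
    return NucleusGeometry.from_mesh("bumpy", bumpy_mesh())


@pytest.fixture(scope="session")
def mesh_sphere_nucleus():
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    return NucleusGeometry.from_mesh("mesh-sphere", mesh)
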