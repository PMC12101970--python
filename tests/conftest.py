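"""Shared fixtures: toy meshes with known geometry, a desk-scale synthetic
dataset, and a model trained on it once per session (reused by the training,
generation and normative-scoring tests)."""

import numpy as np
import pytest

from cardiomesh.meshes import Condition, LabelledMesh, MeshSequence
from cardiomesh.model import ModelConfig, init_state
from cardiomesh.population import PopulationSpec, make_dataset
from cardiomesh.training import TrainConfig, load_split, train

# ---------------------------------------------------------------------------
# toy geometry helpers
# ---------------------------------------------------------------------------

CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (z=0), outward = -z
        [4, 5, 6], [4, 6, 7],  # top
        [0, 1, 5], [0, 5, 4],  # front
        [1, 2, 6], [1, 6, 5],  # right
        [2, 3, 7], [2, 7, 6],  # back
        [3, 0, 4], [3, 4, 7],  # left
    ],
    dtype=np.int64,
)


def cube_vertices(edge: float, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    o = np.asarray(origin, dtype=float)
    unit = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    return o + edge * unit


def tri_part_cube_mesh(lv_edge, myo_edge, rv_edge) -> LabelledMesh:
    """Three disjoint cubes labelled LV / MYO / RV; each part's enclosed
    volume is simply edge^3 (mm^3)."""
    verts = np.concatenate(
        [
            cube_vertices(lv_edge),
            cube_vertices(myo_edge, origin=(100.0, 0, 0)),
            cube_vertices(rv_edge, origin=(0, 100.0, 0)),
        ]
    )
    faces = np.concatenate([CUBE_FACES, CUBE_FACES + 8, CUBE_FACES + 16])
    labels = np.array(["LV"] * 8 + ["MYO"] * 8 + ["RV"] * 8)
    parts = {
        "LV": np.arange(12),
        "MYO": np.arange(12, 24),
        "RV": np.arange(24, 36),
    }
    return LabelledMesh(
        vertices=verts, faces=faces, part_of_vertex=labels, part_surfaces=parts
    )


def cube_sequence(lv_volumes_ml, myo_volume_ml=100.0, rv_volumes_ml=None) -> MeshSequence:
    """Sequence whose per-frame LV (and RV) cavity volumes are prescribed."""
    if rv_volumes_ml is None:
        rv_volumes_ml = lv_volumes_ml
    frames = [
        tri_part_cube_mesh(
            (1000.0 * lv) ** (1 / 3),
            (1000.0 * myo_volume_ml) ** (1 / 3),
            (1000.0 * rv) ** (1 / 3),
        )
        for lv, rv in zip(lv_volumes_ml, rv_volumes_ml)
    ]
    cond = Condition(age=60, sex=0, weight=70, height=162)
    return MeshSequence(frames=frames, condition=cond, subject_id="toy")


@pytest.fixture
def toy_mesh() -> LabelledMesh:
    return tri_part_cube_mesh(10.0, 10.0, 10.0)


# ---------------------------------------------------------------------------
# desk-scale dataset + trained model (session-scoped; built once)
# ---------------------------------------------------------------------------

DESK_SEED = 7
TRAIN_SEED = 11

DESK_SPEC = PopulationSpec(n_subjects=100, T=20, vertices_per_part=162, seed=DESK_SEED)
DESK_MODEL = ModelConfig(T=20, dtype="float32")
DESK_TRAIN = TrainConfig(epochs=50, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """100 healthy subjects (60 train / 20 val / 20 test) at desk scale."""
    root = tmp_path_factory.mktemp("desk_data")
    return make_dataset(DESK_SPEC, root, splits=(0.6, 0.2, 0.2), disease_prevalence=0.0, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_test_split(desk_dataset):
    return load_split(desk_dataset, "test")


@pytest.fixture(scope="session")
def trained_desk(desk_dataset):
    """Model trained on the desk configuration (60 healthy subjects, V=162
    per surface, T=20, 50 epochs, fixed seed). Shared across tests."""
    state, report = train(desk_dataset, DESK_MODEL, DESK_TRAIN)
    return state, report


@pytest.fixture(scope="session")
def untrained_desk(desk_dataset):
    seqs = load_split(desk_dataset, "train")
    return init_state(DESK_MODEL, seqs[0].frames[0], seed=TRAIN_SEED)


# ---------------------------------------------------------------------------
# tiny dataset for fast unit tests
# ---------------------------------------------------------------------------

TINY_SPEC = PopulationSpec(
    n_subjects=6, T=4, vertices_per_part=12, shape_sd=0.2, phenotype_sd=4.0, seed=3
)
TINY_MODEL = ModelConfig(T=4, dtype="float64")


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("tiny_data")
    return make_dataset(TINY_SPEC, root, splits=(0.5, 0.25, 0.25), seed=3)


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    state, report = train(tiny_dataset, TINY_MODEL, TrainConfig(epochs=2, seed=1))
    return state, report
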