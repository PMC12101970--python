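"""Mesh data model, surface metrics, volumes, phenotypes and PLY round trips."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cardiomesh.meshes import (
    Condition,
    LabelledMesh,
    MeshError,
    MeshSequence,
    assd,
    chamfer_distance,
    compute_phenotypes,
    enclosed_volume,
    hausdorff_distance,
    laplacian_smoothness,
    read_mesh_sequence,
    write_mesh_sequence,
)
from cardiomesh.population import generate_sequence, icosphere, PopulationSpec

from conftest import CUBE_FACES, cube_sequence, cube_vertices


def oracle_metrics(a, b):
    """Exhaustive pairwise-distance reference for all three surface metrics."""
    d = cdist(a, b)
    da, db = d.min(axis=1), d.min(axis=0)
    cham = da.mean() + db.mean()
    haus = max(da.max(), db.max())
    avg = (da.sum() + db.sum()) / (len(a) + len(b))
    return cham, haus, avg


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,cham,haus,avg",
    [
        ([(0, 0, 0), (1, 1, 1)], [(0, 0, 0), (1, 1, 1)], 0.0, 0.0, 0.0),
        ([(0, 0, 0)], [(3, 0, 0)], 6.0, 3.0, 3.0),
        ([(0, 0, 0), (2, 0, 0)], [(1, 0, 0)], 2.0, 1.0, 1.0),
        ([(0, 0, 0)], [(5, 0, 0)], 10.0, 5.0, 5.0),
        ([(0, 0, 0), (1, 0, 0)], [(0, 0, 0)], 0.5, 1.0, 1.0 / 3.0),
        ([(0, 0, 0)], [(4, 0, 0)], 8.0, 4.0, 4.0),
    ],
)
def test_distance_hand_examples(a, b, cham, haus, avg):
    a, b = np.array(a, dtype=float), np.array(b, dtype=float)
    assert chamfer_distance(a, b) == pytest.approx(cham, abs=1e-12)
    assert hausdorff_distance(a, b) == pytest.approx(haus, abs=1e-12)
    assert assd(a, b) == pytest.approx(avg, abs=1e-12)


def test_distances_match_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(50):
        a = rng.normal(scale=20, size=(rng.integers(1, 101), 3))
        b = rng.normal(scale=20, size=(rng.integers(1, 101), 3))
        cham, haus, avg = oracle_metrics(a, b)
        assert chamfer_distance(a, b) == pytest.approx(cham, abs=1e-9)
        assert hausdorff_distance(a, b) == pytest.approx(haus, abs=1e-9)
        assert assd(a, b) == pytest.approx(avg, abs=1e-9)
        # symmetry and non-negativity
        assert chamfer_distance(b, a) == pytest.approx(chamfer_distance(a, b), abs=1e-9)
        assert hausdorff_distance(b, a) == pytest.approx(hausdorff_distance(a, b), abs=1e-9)
        assert assd(b, a) == pytest.approx(assd(a, b), abs=1e-9)
        assert min(cham, haus, avg) >= 0


def test_distances_zero_iff_equal_sets():
    a = np.array([[0.0, 0, 0], [1, 2, 3]])
    shuffled = a[::-1].copy()
    assert hausdorff_distance(a, shuffled) == 0.0
    b = a + [[0.1, 0, 0], [0, 0, 0]]
    assert hausdorff_distance(a, b) > 0


def test_distance_empty_set_rejected():
    with pytest.raises(MeshError):
        chamfer_distance(np.empty((0, 3)), np.ones((2, 3)))


# ---------------------------------------------------------------------------
# Laplacian smoothness
# ---------------------------------------------------------------------------


def test_laplacian_path_graph_toy():
    # collinear vertices 0,1,2: endpoints have offset 1, middle 0 -> mean 2/3
    v = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    edges = np.array([[0, 1], [1, 2]])
    assert laplacian_smoothness(v, edges) == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_laplacian_invariances():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(10, 3))
    edges = np.array([[i, (i + 1) % 10] for i in range(10)])
    base = laplacian_smoothness(v, edges)
    assert laplacian_smoothness(v + [5.0, -3.0, 2.0], edges) == pytest.approx(base, rel=1e-12)
    assert laplacian_smoothness(3.0 * v, edges) == pytest.approx(3.0 * base, rel=1e-9)
    assert laplacian_smoothness(np.zeros((4, 3)), np.array([[0, 1], [1, 2], [2, 3], [3, 0]])) == 0.0


def test_laplacian_isolated_vertex_rejected():
    with pytest.raises(MeshError):
        laplacian_smoothness(np.zeros((3, 3)), np.array([[0, 1]]))


# ---------------------------------------------------------------------------
# enclosed volume
# ---------------------------------------------------------------------------


def test_cube_volume_exact():
    # 10 mm cube = 1000 mm^3 = 1 ml
    assert enclosed_volume(cube_vertices(10.0), CUBE_FACES) == pytest.approx(1.0, abs=1e-12)


def test_icosphere_volume_close_to_analytic():
    v, f = icosphere(642)  # subdivision 3
    vol = enclosed_volume(10.0 * v, f)
    assert vol == pytest.approx(4.0 / 3.0 * np.pi, rel=0.02)


def test_flat_degenerate_surface_zero_volume():
    v = cube_vertices(10.0)
    v[:, 2] = 0.0
    assert enclosed_volume(v, CUBE_FACES) == pytest.approx(0.0, abs=1e-12)


def test_volume_rigid_motion_invariance_and_additivity():
    rng = np.random.default_rng(1)
    v, f = icosphere(162)
    base = enclosed_volume(12.0 * v, f)
    # random rotation (QR of a Gaussian matrix) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = 12.0 * v @ q.T + [30.0, -11.0, 7.0]
    assert enclosed_volume(moved, f) == pytest.approx(base, rel=1e-9)
    # two disjoint closed spheres: volumes add
    both_v = np.concatenate([12.0 * v, 5.0 * v + [100.0, 0, 0]])
    both_f = np.concatenate([f, f + len(v)])
    assert enclosed_volume(both_v, both_f) == pytest.approx(
        base + enclosed_volume(5.0 * v, f), rel=1e-9
    )


def test_open_surface_rejected():
    v = cube_vertices(10.0)
    with pytest.raises(MeshError):
        enclosed_volume(v, CUBE_FACES[:-1])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def test_phenotypes_from_prescribed_volume_curve():
    seq = cube_sequence([120.0, 90.0, 48.0, 90.0], myo_volume_ml=100.0)
    rec = compute_phenotypes(seq)
    assert rec.LVEDV == pytest.approx(120.0, rel=1e-9)
    assert rec.LVESV == pytest.approx(48.0, rel=1e-9)
    assert rec.LVEF == pytest.approx(60.0, rel=1e-9)
    assert rec.ed_frame == 0 and rec.es_frame == 2
    # myocardial mass: 100 ml wall volume at ED times 1.05 g/ml
    assert rec.LVM == pytest.approx(105.0, rel=1e-9)


def test_phenotypes_constant_sequence_tie_break():
    rec = compute_phenotypes(cube_sequence([90.0, 90.0, 90.0]))
    assert rec.LVEF == 0.0
    assert rec.ed_frame == rec.es_frame == 0


def test_phenotype_invariants_on_generated_subject():
    spec = PopulationSpec(T=10, vertices_per_part=42, seed=5)
    c = Condition(age=55, sex=1, weight=80, height=180)
    rec = compute_phenotypes(generate_sequence(c, spec, seed=5))
    assert 0 <= rec.LVEF <= 100
    assert rec.LVESV <= rec.LVEDV
    assert min(rec.LVEDV, rec.RVEDV, rec.LVM) > 0


# ---------------------------------------------------------------------------
# validation + serialization
# ---------------------------------------------------------------------------


def test_validation_rejects_bad_meshes(toy_mesh):
    bad = LabelledMesh(
        vertices=toy_mesh.vertices,
        faces=toy_mesh.faces,
        part_of_vertex=toy_mesh.part_of_vertex,
        part_surfaces={"LV": toy_mesh.part_surfaces["LV"][:-1]},  # open surface
    )
    with pytest.raises(MeshError, match="not closed"):
        bad.validate()
    with pytest.raises(MeshError):
        MeshSequence(frames=[], condition=Condition(60, 0, 70, 162))


def test_write_read_round_trip(tmp_path):
    seq = cube_sequence([120.0, 60.0])
    write_mesh_sequence(seq, tmp_path / "seq")
    back = read_mesh_sequence(tmp_path / "seq")
    assert back.T == 2
    assert back.subject_id == seq.subject_id
    assert back.condition == seq.condition
    for a, b in zip(seq.frames, back.frames):
        np.testing.assert_allclose(a.vertices, b.vertices, atol=1e-6)
        assert np.array_equal(a.faces, b.faces)
        assert np.array_equal(a.part_of_vertex, b.part_of_vertex)


def test_write_refuses_overwrite_without_flag(tmp_path):
    seq = cube_sequence([120.0, 60.0])
    write_mesh_sequence(seq, tmp_path / "seq")
    with pytest.raises(FileExistsError):
        write_mesh_sequence(seq, tmp_path / "seq")
    write_mesh_sequence(seq, tmp_path / "seq", overwrite=True)  # allowed


def test_read_missing_frame(tmp_path):
    seq = cube_sequence([120.0, 60.0, 80.0])
    write_mesh_sequence(seq, tmp_path / "seq")
    (tmp_path / "seq" / "frame_001.ply").unlink()
    with pytest.raises(MeshError, match="missing frame"):
        read_mesh_sequence(tmp_path / "seq")


def test_read_topology_drift(tmp_path):
    seq = cube_sequence([120.0, 60.0])
    write_mesh_sequence(seq, tmp_path / "seq")
    # rewrite frame 1 with one extra vertex
    from cardiomesh.meshes import _write_ply

    f1 = seq.frames[1]
    _write_ply(
        tmp_path / "seq" / "frame_001.ply",
        np.concatenate([f1.vertices, [[0.0, 0, 0]]]),
        f1.faces,
    )
    with pytest.raises(MeshError, match="topology mismatch"):
        read_mesh_sequence(tmp_path / "seq")
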