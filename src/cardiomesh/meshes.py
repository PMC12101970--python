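"""Mesh data model, serialization, surface metrics and cardiac phenotypes.

The central objects are :class:`LabelledMesh` — one frame of a biventricular
surface mesh with three labelled anatomical parts (LV cavity, myocardium, RV
cavity), each a closed oriented triangle surface — and :class:`MeshSequence`,
an ordered series of frames over one cardiac cycle sharing a fixed topology.

Coordinates are millimetres throughout; enclosed volumes are reported in
millilitres and myocardial mass in grams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

PARTS = ("LV", "MYO", "RV")

#: myocardial tissue density used to convert wall volume to mass (g/ml)
MYOCARDIUM_DENSITY_G_PER_ML = 1.05

PHENOTYPE_CSV_COLUMNS = (
    "LVEDV",
    "LVESV",
    "LVEF",
    "LVM",
    "RVEDV",
    "RVESV",
    "RVEF",
    "ed_frame",
    "es_frame",
)


class MeshError(ValueError):
    """Raised for invalid mesh data or inconsistent sequences."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """Clinical conditioning factors for one subject.

    Parameters
    ----------
    age : float
        Age in years (18-100).
    sex : int
        0 = female, 1 = male.
    weight : float
        Body weight in kg (30-200).
    height : float
        Standing height in cm (120-220).
    """

    age: float
    sex: int
    weight: float
    height: float

    def __post_init__(self) -> None:
        if not (18.0 <= self.age <= 100.0):
            raise ValueError(f"age {self.age} outside [18, 100]")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {self.sex}")
        if not (30.0 <= self.weight <= 200.0):
            raise ValueError(f"weight {self.weight} outside [30, 200] kg")
        if not (120.0 <= self.height <= 220.0):
            raise ValueError(f"height {self.height} outside [120, 220] cm")

    @property
    def bsa(self) -> float:
        """Body surface area (m^2) by the Mosteller formula."""
        return float(np.sqrt(self.weight * self.height / 3600.0))

    def to_dict(self) -> dict:
        return {
            "age_years": float(self.age),
            "sex": int(self.sex),
            "weight_kg": float(self.weight),
            "height_cm": float(self.height),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        return cls(
            age=float(d["age_years"]),
            sex=int(d["sex"]),
            weight=float(d["weight_kg"]),
            height=float(d["height_cm"]),
        )


@dataclass
class LabelledMesh:
    """One frame's triangulated biventricular surface.

    ``vertices`` is V x 3 (mm); ``faces`` is F x 3 with 0-based indices and
    counter-clockwise orientation giving outward normals; ``part_of_vertex``
    labels each vertex LV / MYO / RV; ``part_surfaces`` maps each part to the
    face indices forming its closed surface.
    """

    vertices: np.ndarray
    faces: np.ndarray
    part_of_vertex: np.ndarray
    part_surfaces: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.part_of_vertex = np.asarray(self.part_of_vertex)
        self.part_surfaces = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.part_surfaces.items()
        }

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        V = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be V x 3")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be F x 3")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= V:
            raise MeshError("face index out of range")
        if len(self.part_of_vertex) != V:
            raise MeshError("part_of_vertex length mismatch")
        referenced = np.zeros(V, dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            raise MeshError("unreferenced vertex present")
        for part, face_idx in self.part_surfaces.items():
            if part not in PARTS:
                raise MeshError(f"unknown part label {part!r}")
            _require_closed_oriented(self.faces[face_idx], part)

    # -- convenience --------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def part_vertex_indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.part_of_vertex == part)

    def part_vertices(self, part: str) -> np.ndarray:
        return self.vertices[self.part_vertex_indices(part)]

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E x 2, sorted pairs) of the full mesh."""
        return _face_edges_unique(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "LabelledMesh":
        return replace(self, vertices=np.asarray(vertices, dtype=np.float64))


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )


def _face_edges_unique(faces: np.ndarray) -> np.ndarray:
    e = np.sort(_directed_edges(faces), axis=1)
    return np.unique(e, axis=0)


def _require_closed_oriented(faces: np.ndarray, part: str) -> None:
    """Every undirected edge must be used exactly twice, once per direction."""
    if len(faces) == 0:
        raise MeshError(f"part {part} has no faces")
    d = _directed_edges(faces)
    und = np.sort(d, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise MeshError(f"part {part} surface is not closed (non-manifold edge)")
    # orientation: each directed edge must be unique (i.e. the two uses of an
    # undirected edge run in opposite directions)
    _, dcounts = np.unique(d, axis=0, return_counts=True)
    if not np.all(dcounts == 1):
        raise MeshError(f"part {part} surface is not consistently oriented")


@dataclass
class MeshSequence:
    """T ordered frames of one cardiac cycle plus the subject's conditions."""

    frames: List[LabelledMesh]
    condition: Condition
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise MeshError("a mesh sequence needs at least 2 frames")

    def validate(self) -> None:
        ref = self.frames[0]
        ref.validate()
        for t, fr in enumerate(self.frames[1:], start=1):
            if fr.vertices.shape != ref.vertices.shape:
                raise MeshError(f"topology mismatch at frame {t}: vertex count differs")
            if not np.array_equal(fr.faces, ref.faces):
                raise MeshError(f"topology mismatch at frame {t}: faces differ")
            if not np.array_equal(fr.part_of_vertex, ref.part_of_vertex):
                raise MeshError(f"topology mismatch at frame {t}: labels differ")
            if not np.all(np.isfinite(fr.vertices)):
                raise MeshError(f"non-finite vertices at frame {t}")

    @property
    def T(self) -> int:
        return len(self.frames)

    def vertex_array(self) -> np.ndarray:
        """Stacked T x V x 3 vertex coordinates."""
        return np.stack([f.vertices for f in self.frames])


@dataclass(frozen=True)
class PhenotypeRecord:
    """Ventricular volumes (ml), ejection fractions (%) and LV mass (g)."""

    LVEDV: float
    LVESV: float
    LVEF: float
    LVM: float
    RVEDV: float
    RVESV: float
    RVEF: float
    ed_frame: int = 0
    es_frame: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PHENOTYPE_CSV_COLUMNS}


# ---------------------------------------------------------------------------
# surface distance metrics
# ---------------------------------------------------------------------------


def _as_points(x) -> np.ndarray:
    p = np.asarray(x, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) == 0:
        raise MeshError("point set must be a non-empty N x 3 array")
    return p


def _nn_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(b).query(a)
    return d


def chamfer_distance(a, b) -> float:
    """Symmetric Chamfer distance: sum of the two mean nearest-neighbour
    distances between point sets ``a`` and ``b`` (mm)."""
    a, b = _as_points(a), _as_points(b)
    return float(_nn_dists(a, b).mean() + _nn_dists(b, a).mean())


def hausdorff_distance(a, b) -> float:
    """Symmetric Hausdorff distance: worst-case nearest-neighbour mismatch."""
    a, b = _as_points(a), _as_points(b)
    return float(max(_nn_dists(a, b).max(), _nn_dists(b, a).max()))


def assd(a, b) -> float:
    """Average symmetric surface distance between two vertex sets (mm)."""
    a, b = _as_points(a), _as_points(b)
    return float((_nn_dists(a, b).sum() + _nn_dists(b, a).sum()) / (len(a) + len(b)))


# ---------------------------------------------------------------------------
# smoothness, volume, phenotypes
# ---------------------------------------------------------------------------


def neighbour_operator(edges: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    """Row-stochastic sparse operator averaging each vertex's neighbours."""
    edges = np.asarray(edges, dtype=np.int64)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)
    )
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise MeshError("isolated vertex (no neighbours)")
    inv = sparse.diags(1.0 / deg)
    return (inv @ adj).tocsr()

def laplacian_smoothness(vertices, edges) -> float:
    """Mean, over vertices, of the norm of the mean neighbour-offset vector.

    Zero for coincident or perfectly 'balanced' neighbourhoods; invariant to
    global translation and linear in uniform scaling.
    """
    v = np.asarray(vertices, dtype=np.float64)
    op = neighbour_operator(edges, len(v))
    offsets = op @ v - v
    return float(np.linalg.norm(offsets, axis=1).mean())


def enclosed_volume(vertices, faces) -> float:
    """Volume (ml) enclosed by a closed, outward-oriented triangle surface.

    Uses the divergence theorem: the sum of signed tetrahedra spanned by each
    face and the origin. The absolute value is returned, so a consistently
    inward-oriented surface gives the same magnitude.
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    _require_closed_oriented(f, "surface")
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    signed_mm3 = np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0
    return float(abs(signed_mm3) / 1000.0)


def part_volume(mesh: LabelledMesh, part: str) -> float:
    """Enclosed volume (ml) of one labelled part surface."""
    return enclosed_volume(mesh.vertices, mesh.faces[mesh.part_surfaces[part]])


def compute_phenotypes(seq: MeshSequence) -> PhenotypeRecord:
    """Derive ventricular volumes, ejection fractions and LV mass.

    ED is the frame of maximum LV cavity volume and ES the frame of minimum
    (ties broken to the earliest frame). LV mass is the myocardial wall
    volume at ED times the tissue density of 1.05 g/ml.
    """
    lv = np.array([part_volume(f, "LV") for f in seq.frames])
    rv = np.array([part_volume(f, "RV") for f in seq.frames])
    ed, es = int(np.argmax(lv)), int(np.argmin(lv))
    lvedv, lvesv = float(lv[ed]), float(lv[es])
    rvedv, rvesv = float(rv[ed]), float(rv[es])
    if lvedv <= 0:
        raise MeshError("zero LV end-diastolic volume")
    myo_wall = part_volume(seq.frames[ed], "MYO")
    return PhenotypeRecord(
        LVEDV=lvedv,
        LVESV=lvesv,
        LVEF=(lvedv - lvesv) / lvedv * 100.0,
        LVM=myo_wall * MYOCARDIUM_DENSITY_G_PER_ML,
        RVEDV=rvedv,
        RVESV=rvesv,
        RVEF=(rvedv - rvesv) / rvedv * 100.0 if rvedv > 0 else 0.0,
        ed_frame=ed,
        es_frame=es,
    )


# ---------------------------------------------------------------------------
# PLY + manifest serialization
# ---------------------------------------------------------------------------

_PLY_HEADER = """ply
format binary_little_endian 1.0
comment cardiomesh frame
element vertex {nv}
property double x
property double y
property double z
element face {nf}
property list uchar int32 vertex_indices
end_header
"""


def _write_ply(path: Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    nv, nf = len(vertices), len(faces)
    face_rec = np.empty(nf, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    face_rec["n"] = 3
    face_rec["idx"] = faces.astype("<i4")
    with open(path, "wb") as fh:
        fh.write(_PLY_HEADER.format(nv=nv, nf=nf).encode("ascii"))
        fh.write(np.ascontiguousarray(vertices, dtype="<f8").tobytes())
        fh.write(face_rec.tobytes())


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        header = b""
        while not header.endswith(b"end_header\n"):
            line = fh.readline()
            if not line:
                raise MeshError(f"{path}: truncated PLY header")
            header += line
        lines = header.decode("ascii").splitlines()
        if "format binary_little_endian 1.0" not in lines[1]:
            raise MeshError(f"{path}: unsupported PLY format")
        nv = nf = 0
        vert_props: list[str] = []
        current = None
        for ln in lines:
            tok = ln.split()
            if not tok:
                continue
            if tok[0] == "element":
                current = tok[1]
                if tok[1] == "vertex":
                    nv = int(tok[2])
                elif tok[1] == "face":
                    nf = int(tok[2])
            elif tok[0] == "property" and current == "vertex" and tok[1] != "list":
                vert_props.append(tok[1])
        if vert_props[:3] != ["double", "double", "double"]:
            raise MeshError(f"{path}: expected double x/y/z vertex properties")
        vertices = np.frombuffer(fh.read(nv * 24), dtype="<f8").reshape(nv, 3).copy()
        face_rec = np.frombuffer(
            fh.read(nf * 13), dtype=[("n", "u1"), ("idx", "<i4", (3,))]
        )
        if not np.all(face_rec["n"] == 3):
            raise MeshError(f"{path}: non-triangular face")
        return vertices, face_rec["idx"].astype(np.int64)


def write_mesh_sequence(seq: MeshSequence, path, overwrite: bool = False) -> None:
    """Write one PLY per frame plus ``manifest.json`` describing the sequence."""
    seq.validate()
    out = Path(path)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    ref = seq.frames[0]
    manifest = {
        "format_version": 1,
        "subject_id": seq.subject_id,
        "T": seq.T,
        "condition": seq.condition.to_dict(),
        "part_of_vertex": [str(p) for p in ref.part_of_vertex],
        "part_surfaces": {k: v.tolist() for k, v in ref.part_surfaces.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest))
    for t, frame in enumerate(seq.frames):
        _write_ply(out / f"frame_{t:03d}.ply", frame.vertices, frame.faces)


def read_mesh_sequence(path) -> MeshSequence:
    """Read and validate a sequence written by :func:`write_mesh_sequence`."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    T = int(manifest["T"])
    labels = np.array(manifest["part_of_vertex"])
    parts = {k: np.asarray(v, dtype=np.int64) for k, v in manifest["part_surfaces"].items()}
    frames: List[LabelledMesh] = []
    ref_shape = None
    ref_faces = None
    for t in range(T):
        fp = root / f"frame_{t:03d}.ply"
        if not fp.exists():
            raise MeshError(f"missing frame file {fp.name}")
        vertices, faces = _read_ply(fp)
        if ref_shape is None:
            ref_shape, ref_faces = vertices.shape, faces
        elif vertices.shape != ref_shape or not np.array_equal(faces, ref_faces):
            raise MeshError(f"topology mismatch at frame {t}")
        frames.append(
            LabelledMesh(
                vertices=vertices,
                faces=faces,
                part_of_vertex=labels,
                part_surfaces=parts,
            )
        )
    seq = MeshSequence(
        frames=frames,
        condition=Condition.from_dict(manifest["condition"]),
        subject_id=str(manifest["subject_id"]),
    )
    seq.validate()
    return seq
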