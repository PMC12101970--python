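"""Seeded synthetic population of beating biventricular mesh sequences.

Stands in for access-controlled cine-CMR-derived cohorts: each subject gets
clinical conditions (age, sex, weight, height), condition-dependent ground
truth phenotypes (volumes, ejection fractions, mass), and a 3D+t mesh
sequence built from an icosphere-based biventricular template — LV cavity as
a prolate ellipsoid, myocardium as a closed shell between endo- and
epicardial ellipsoids, RV as a flattened lateral ellipsoid. Contraction is
radial scaling about the long axis with a raised-cosine systolic phase, so
the LV volume curve interpolates EDV -> ESV -> EDV with end-systole at a
configurable fraction of the cycle. Optional disease perturbations emulate
dilatation, hypertrophy and reduced contraction.

All randomness flows from explicit seeds; noise-free generation is an exact
closed-form function of the conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .meshes import (
    Condition,
    LabelledMesh,
    MeshSequence,
    PhenotypeRecord,
    write_mesh_sequence,
)

DISEASE_KINDS = ("dilated", "hypertrophic", "low_ef")

DATASET_CSV_COLUMNS = (
    "subject_id",
    "split",
    "age",
    "sex",
    "weight",
    "height",
    "label",
    "true_LVEDV",
    "true_LVESV",
    "true_LVEF",
    "true_LVM",
    "true_RVEDV",
    "true_RVESV",
    "true_RVEF",
)


@dataclass(frozen=True)
class PopulationSpec:
    """Generator configuration; defaults give a realistic adult population
    at desk scale (162 vertices per surface, 20 frames per cycle)."""

    n_subjects: int = 50
    T: int = 20
    vertices_per_part: int = 162
    es_fraction: float = 0.35
    # linear effect coefficients for the ground-truth phenotype model
    edv_base: float = 90.0   # ml, intercept of LVEDV
    edv_bsa: float = 30.0    # ml per m^2 body surface area
    edv_sex: float = 20.0    # ml added for male sex
    edv_age: float = 0.3     # ml lost per year beyond age 60
    ef_base: float = 60.0    # % LVEF at age 60
    ef_age: float = 2.0      # % LVEF lost per decade beyond 60
    rv_ratio: float = 1.1    # RV volumes relative to LV
    wall_base: float = 85.0  # ml LV wall volume, female
    wall_sex: float = 30.0   # ml added for male sex
    shape_sd: float = 0.5    # mm, smooth per-subject shape noise
    phenotype_sd: float = 8.0  # ml-scale SD of phenotype noise (0 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if not (0.0 < self.es_fraction < 1.0):
            raise ValueError("es_fraction must lie in (0, 1)")
        if self.shape_sd < 0 or self.phenotype_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class DiseaseSpec:
    """A named perturbation applied to the ground-truth phenotypes."""

    kind: str
    severity: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in DISEASE_KINDS:
            raise ValueError(f"unknown disease kind {self.kind!r}; choose from {DISEASE_KINDS}")
        if not (0.0 < self.severity <= 1.0):
            raise ValueError("severity must lie in (0, 1]")


# ---------------------------------------------------------------------------
# conditions and ground-truth phenotypes
# ---------------------------------------------------------------------------


def sample_conditions(spec: PopulationSpec, n: int, seed: int) -> List[Condition]:
    """Draw ``n`` subjects' clinical conditions.

    Sex is Bernoulli(0.5); age Uniform(45, 80) years; height and weight are
    sex-specific normals (clipped to the physiological ranges of
    :class:`~cardiomesh.meshes.Condition`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(45.0, 80.0, size=n)
    height = np.where(
        sex == 0, rng.normal(162.0, 7.0, size=n), rng.normal(176.0, 7.0, size=n)
    )
    weight = np.where(
        sex == 0, rng.normal(70.0, 12.0, size=n), rng.normal(84.0, 13.0, size=n)
    )
    height = np.clip(height, 120.0, 220.0)
    weight = np.clip(weight, 30.0, 200.0)
    return [
        Condition(age=float(age[i]), sex=int(sex[i]), weight=float(weight[i]), height=float(height[i]))
        for i in range(n)
    ]


def true_phenotypes(
    c: Condition,
    spec: PopulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeRecord:
    """Closed-form condition -> phenotype model (the generator ground truth).

    LVEDV rises with body surface area and male sex and falls slowly with
    age; LVEF falls with age (clipped to [35, 75]%); RV quantities scale the
    LV ones by ``rv_ratio``; LV mass comes from a sex-dependent wall volume
    at 1.05 g/ml. With ``rng`` (and ``phenotype_sd`` > 0) additive Gaussian
    noise is applied; otherwise the record is deterministic.
    """
    sd = spec.phenotype_sd if rng is not None else 0.0

    def noise(scale: float) -> float:
        return float(rng.normal(0.0, scale)) if sd > 0 else 0.0

    bsa = c.bsa
    lvedv = (
        spec.edv_base
        + spec.edv_bsa * bsa
        + spec.edv_sex * c.sex
        - spec.edv_age * (c.age - 60.0)
        + noise(sd)
    )
    lvedv = max(lvedv, 40.0)
    lvef = spec.ef_base - spec.ef_age * (c.age - 60.0) / 10.0 + noise(0.4 * sd)
    lvef = float(np.clip(lvef, 35.0, 75.0))
    lvesv = lvedv * (1.0 - lvef / 100.0)
    rvedv = spec.rv_ratio * lvedv
    rvef = lvef
    rvesv = rvedv * (1.0 - rvef / 100.0)
    wall = max(spec.wall_base + spec.wall_sex * c.sex + noise(0.8 * sd), 20.0)
    return PhenotypeRecord(
        LVEDV=lvedv,
        LVESV=lvesv,
        LVEF=lvef,
        LVM=wall * 1.05,
        RVEDV=rvedv,
        RVESV=rvesv,
        RVEF=rvef,
        ed_frame=0,
        es_frame=int(round(spec.es_fraction * spec.T)),
    )


def apply_disease(rec: PhenotypeRecord, disease: DiseaseSpec) -> PhenotypeRecord:
    """Perturb ground-truth phenotypes for one of the named disease kinds."""
    s = disease.severity
    lvedv, lvesv, lvm = rec.LVEDV, rec.LVESV, rec.LVM
    rvedv, rvesv = rec.RVEDV, rec.RVESV
    if disease.kind == "dilated":
        lvedv *= 1.0 + 0.4 * s
        rvedv *= 1.0 + 0.4 * s
        lvesv = lvedv * (1.0 - rec.LVEF / 100.0)
        rvesv = rvedv * (1.0 - rec.RVEF / 100.0)
    elif disease.kind == "hypertrophic":
        lvm *= 1.0 + 0.6 * s
    elif disease.kind == "low_ef":
        lvesv = lvedv - (lvedv - lvesv) * (1.0 - 0.5 * s)
        rvesv = rvedv - (rvedv - rvesv) * (1.0 - 0.5 * s)
    lvef = (lvedv - lvesv) / lvedv * 100.0
    rvef = (rvedv - rvesv) / rvedv * 100.0
    return PhenotypeRecord(
        LVEDV=lvedv, LVESV=lvesv, LVEF=lvef, LVM=lvm,
        RVEDV=rvedv, RVESV=rvesv, RVEF=rvef,
        ed_frame=rec.ed_frame, es_frame=rec.es_frame,
    )


# ---------------------------------------------------------------------------
# icosphere template
# ---------------------------------------------------------------------------


def icosphere(n_vertices: int) -> Tuple[np.ndarray, np.ndarray]:
    """Unit icosphere with ``n_vertices`` in {12, 42, 162, 642, 2562, ...}
    (10 * 4^s + 2), outward counter-clockwise faces."""
    levels = {10 * 4**s + 2: s for s in range(7)}
    if n_vertices not in levels:
        raise ValueError(
            f"vertices_per_part must be one of {sorted(levels)[:5]}..., got {n_vertices}"
        )
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(levels[n_vertices]):
        v, f = _subdivide(v, f)
    # ensure outward orientation (positive signed volume)
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum()
    if signed < 0:
        f = f[:, [0, 2, 1]]
    return v, f


def _subdivide(v: np.ndarray, f: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    verts = list(map(tuple, v))
    cache: Dict[Tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(tuple(m))
        return cache[key]

    new_faces = []
    for a, b, c in f:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts, dtype=np.float64), np.array(new_faces, dtype=np.int64)


# discrete unit-icosphere volume so target volumes are matched exactly
def _unit_sphere_mesh_volume(v: np.ndarray, f: np.ndarray) -> float:
    return float(
        np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    )


class BiventricularTemplate:
    """Fixed-topology biventricular template built from four icosphere
    surfaces: LV endocardium, MYO epicardium + inward endocardial copy, RV.

    Vertex blocks (in order): LV (n), MYO outer (n), MYO inner (n), RV (n).
    """

    LONG_AXIS_RATIO = 1.5   # z semi-axis over equatorial for LV/epicardium
    RV_AXES = (0.55, 1.0, 1.3)  # relative semi-axes of the RV ellipsoid

    def __init__(self, vertices_per_part: int = 162):
        self.n = vertices_per_part
        sphere_v, sphere_f = icosphere(vertices_per_part)
        self.sphere_v = sphere_v
        self.sphere_f = sphere_f
        self.unit_volume = _unit_sphere_mesh_volume(sphere_v, sphere_f)
        n, nf = len(sphere_v), len(sphere_f)
        flip = sphere_f[:, [0, 2, 1]]
        self.faces = np.concatenate(
            [sphere_f, sphere_f + n, flip + 2 * n, sphere_f + 3 * n]
        )
        self.part_of_vertex = np.array(
            ["LV"] * n + ["MYO"] * (2 * n) + ["RV"] * n
        )
        self.part_surfaces = {
            "LV": np.arange(nf),
            "MYO": np.arange(nf, 3 * nf),
            "RV": np.arange(3 * nf, 4 * nf),
        }

    def scale_for_volume(self, volume_ml: float) -> float:
        """Equatorial semi-axis (mm) of a (a, a, 1.5a) ellipsoid whose
        *discrete* mesh volume equals ``volume_ml``."""
        mm3 = volume_ml * 1000.0
        return float((mm3 / (self.LONG_AXIS_RATIO * self.unit_volume)) ** (1.0 / 3.0))

    def rv_scale_for_volume(self, volume_ml: float) -> float:
        mm3 = volume_ml * 1000.0
        ax, ay, az = self.RV_AXES
        return float((mm3 / (ax * ay * az * self.unit_volume)) ** (1.0 / 3.0))


def _systolic_phase(T: int, es_fraction: float) -> np.ndarray:
    """s(t) in [0, 1]: 0 at frame 0 (ED), 1 at es_fraction*T (ES), raised
    cosine in both contraction and relaxation."""
    t = np.arange(T, dtype=np.float64)
    tes = es_fraction * T
    s = np.where(
        t <= tes,
        0.5 * (1.0 - np.cos(np.pi * t / tes)),
        0.5 * (1.0 - np.cos(np.pi * (T - t) / (T - tes))),
    )
    return s


def _shape_noise_field(rng: np.random.Generator, sd: float, radius: float):
    """Smooth random displacement field: a sum of Gaussian bumps. Returns a
    callable on N x 3 points; the same field is applied to every frame so
    topology and closure are preserved."""
    k = 6
    centres = rng.normal(0.0, radius, size=(k, 3))
    directions = rng.normal(size=(k, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    amps = rng.normal(0.0, sd, size=k)
    widths = rng.uniform(0.4, 0.8, size=k) * radius

    def displace(points: np.ndarray) -> np.ndarray:
        out = np.zeros_like(points)
        for i in range(k):
            d2 = ((points - centres[i]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * widths[i] ** 2))
            out += amps[i] * w[:, None] * directions[i]
        return out

    return displace


def generate_sequence(
    c: Condition,
    spec: PopulationSpec,
    seed: int,
    disease: Optional[DiseaseSpec] = None,
    template: Optional[BiventricularTemplate] = None,
) -> MeshSequence:
    """Generate one subject's beating-heart mesh sequence.

    Frame 0 is end-diastole; per-frame LV volume follows
    ``EDV - (EDV - ESV) * s(t)`` with the raised-cosine phase ``s``;
    the myocardial wall volume is held constant over the cycle. Identical
    topology for every subject, frame and seed.
    """
    rng = np.random.default_rng(seed)
    tpl = template if template is not None else BiventricularTemplate(spec.vertices_per_part)
    rec = true_phenotypes(c, spec, rng if spec.phenotype_sd > 0 else None)
    if disease is not None:
        rec = apply_disease(rec, disease)

    wall_ml = rec.LVM / 1.05
    s = _systolic_phase(spec.T, spec.es_fraction)
    lv_vol = rec.LVEDV - (rec.LVEDV - rec.LVESV) * s
    rv_vol = rec.RVEDV - (rec.RVEDV - rec.RVESV) * s

    a_lv0 = tpl.scale_for_volume(rec.LVEDV)
    a_epi0 = tpl.scale_for_volume(rec.LVEDV + wall_ml)
    a_rv0 = tpl.rv_scale_for_volume(rec.RVEDV)
    rv_axes = np.array(tpl.RV_AXES) * a_rv0
    rv_centre = np.array([a_epi0 + 0.35 * rv_axes[0], 0.0, 0.0])

    displace = None
    if spec.shape_sd > 0:
        displace = _shape_noise_field(rng, spec.shape_sd, radius=1.5 * a_epi0)

    sv = tpl.sphere_v
    lv0 = sv * np.array([a_lv0, a_lv0, tpl.LONG_AXIS_RATIO * a_lv0])
    epi0 = sv * np.array([a_epi0, a_epi0, tpl.LONG_AXIS_RATIO * a_epi0])
    rv0 = sv * rv_axes + rv_centre

    frames = []
    for t in range(spec.T):
        # radial (x, y) scaling about the long axis; volume scales with g^2
        g_lv = np.sqrt(lv_vol[t] / rec.LVEDV)
        g_epi = np.sqrt((lv_vol[t] + wall_ml) / (rec.LVEDV + wall_ml))
        g_rv = np.sqrt(rv_vol[t] / rec.RVEDV)
        lv_t = lv0 * np.array([g_lv, g_lv, 1.0])
        epi_t = epi0 * np.array([g_epi, g_epi, 1.0])
        rv_t = rv_centre + (rv0 - rv_centre) * np.array([g_rv, g_rv, 1.0])
        verts = np.concatenate([lv_t, epi_t, lv_t.copy(), rv_t])
        if displace is not None:
            verts = verts + displace(verts)
        frames.append(
            LabelledMesh(
                vertices=verts,
                faces=tpl.faces,
                part_of_vertex=tpl.part_of_vertex,
                part_surfaces=tpl.part_surfaces,
            )
        )
    return MeshSequence(frames=frames, condition=c, subject_id="synthetic")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def make_dataset(
    spec: PopulationSpec,
    out_dir,
    splits: Sequence[float] = (0.6, 0.2, 0.2),
    disease_prevalence: float = 0.0,
    seed: Optional[int] = None,
    write_meshes: bool = True,
) -> dict:
    """Generate a population, write sequences + tables, return the manifest.

    Subjects are split into train/val/test; the training split contains
    healthy subjects only (disease labels are assigned only outside it, with
    the given prevalence; kind uniform over the named kinds, severity
    Uniform(0.5, 1)). Writes one directory per subject, ``dataset.csv``
    (conditions, labels and ground-truth phenotypes) and ``splits.json``.
    """
    if abs(sum(splits) - 1.0) > 1e-8 or len(splits) != 3 or min(splits) < 0:
        raise ValueError("splits must be three non-negative fractions summing to 1")
    if not (0.0 <= disease_prevalence <= 1.0):
        raise ValueError("disease_prevalence must lie in [0, 1]")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    conditions = sample_conditions(spec, n, seed=int(rng.integers(2**31)))

    counts = [int(np.floor(f * n)) for f in splits]
    counts[0] += n - sum(counts)  # remainder to train
    split_of = np.array(
        ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    )
    rng.shuffle(split_of)

    template = BiventricularTemplate(spec.vertices_per_part)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    subjects = []
    for i, (c, split) in enumerate(zip(conditions, split_of)):
        sid = f"sub-{i:04d}"
        disease = None
        label = "healthy"
        if split != "train" and rng.random() < disease_prevalence:
            kind = DISEASE_KINDS[int(rng.integers(len(DISEASE_KINDS)))]
            disease = DiseaseSpec(kind=kind, severity=float(rng.uniform(0.5, 1.0)))
            label = kind
        seq_seed = int(rng.integers(2**31))
        rec = true_phenotypes(
            c, spec, np.random.default_rng(seq_seed) if spec.phenotype_sd > 0 else None
        )
        if disease is not None:
            rec = apply_disease(rec, disease)
        if write_meshes:
            seq = generate_sequence(c, spec, seed=seq_seed, disease=disease, template=template)
            seq.subject_id = sid
            write_mesh_sequence(seq, out / sid, overwrite=True)
        rows.append(
            {
                "subject_id": sid,
                "split": split,
                "age": round(c.age, 6),
                "sex": c.sex,
                "weight": round(c.weight, 6),
                "height": round(c.height, 6),
                "label": label,
                "true_LVEDV": round(rec.LVEDV, 6),
                "true_LVESV": round(rec.LVESV, 6),
                "true_LVEF": round(rec.LVEF, 6),
                "true_LVM": round(rec.LVM, 6),
                "true_RVEDV": round(rec.RVEDV, 6),
                "true_RVESV": round(rec.RVESV, 6),
                "true_RVEF": round(rec.RVEF, 6),
            }
        )
        subjects.append({"subject_id": sid, "split": split, "label": label, "seed": seq_seed})

    df = pd.DataFrame(rows, columns=list(DATASET_CSV_COLUMNS))
    df.to_csv(out / "dataset.csv", index=False)
    manifest = {
        "root": str(out),
        "csv": str(out / "dataset.csv"),
        "seed": seed,
        "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        "splits": {
            name: [s["subject_id"] for s in subjects if s["split"] == name]
            for name in ("train", "val", "test")
        },
        "subjects": subjects,
    }
    (out / "splits.json").write_text(json.dumps(manifest, indent=1))
    return manifest
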