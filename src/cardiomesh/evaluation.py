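"""Reconstruction/generation evaluation, latent deltas and downstream harnesses.

Covers four analyses around a trained model:

* surface-accuracy tables (Hausdorff distance and average symmetric surface
  distance, per anatomical structure, at ED, ES and over all frames);
* distribution similarity (histogram KL divergence and 1-D Wasserstein
  distance) between real and generated phenotype samples, optionally
  stratified by conditioning variables;
* the personalized normative deviation score: the latent delta, i.e. the
  Euclidean distance between a subject's latent vector and the mean latent
  vector of condition-matched synthetic hearts;
* disease-classification and outcome-association harnesses (AUC over seeded
  splits; single-covariate logistic score tests with Bonferroni control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .meshes import (
    MeshSequence,
    PHENOTYPE_CSV_COLUMNS,
    assd,
    compute_phenotypes,
    hausdorff_distance,
)
from .model import (
    ModelState,
    batch_latent_vectors,
    decode_samples,
    latent_vector,
    reconstruct,
)

PHENOTYPE_NAMES = tuple(c for c in PHENOTYPE_CSV_COLUMNS if c not in ("ed_frame", "es_frame"))

STRUCTURES = ("LV", "MYO", "RV")


# ---------------------------------------------------------------------------
# reconstruction evaluation
# ---------------------------------------------------------------------------


def _pair_table(inp: MeshSequence, rec: MeshSequence) -> pd.DataFrame:
    """HD/ASSD per structure at ED, ES and averaged over frames for one
    input/reconstruction pair."""
    phen = compute_phenotypes(inp)
    frames_of = {"ed": [phen.ed_frame], "es": [phen.es_frame], "all": range(inp.T)}
    rows = []
    for structure in STRUCTURES:
        idx = inp.frames[0].part_vertex_indices(structure)
        for when, frames in frames_of.items():
            hd, sd = [], []
            for t in frames:
                a = inp.frames[t].vertices[idx]
                b = rec.frames[t].vertices[idx]
                hd.append(hausdorff_distance(a, b))
                sd.append(assd(a, b))
            rows.append(
                {"structure": structure, "frames": when, "HD": np.mean(hd), "ASSD": np.mean(sd)}
            )
    df = pd.DataFrame(rows)
    mean_rows = (
        df.groupby("frames", as_index=False)[["HD", "ASSD"]].mean().assign(structure="mean")
    )
    return pd.concat([df, mean_rows], ignore_index=True)


def evaluate_reconstruction(
    state: ModelState,
    sequences: Sequence[MeshSequence],
    reconstructions: Optional[Sequence[MeshSequence]] = None,
) -> pd.DataFrame:
    """Mean-over-subjects HD/ASSD table (structure x {ed, es, all}).

    ``reconstructions`` may be supplied (e.g. for oracle checks); otherwise
    each sequence is reconstructed with the model in evaluation mode.
    """
    if not sequences:
        raise ValueError("empty evaluation split")
    tables = []
    for i, seq in enumerate(sequences):
        rec = reconstructions[i] if reconstructions is not None else reconstruct(seq, state)
        tables.append(_pair_table(seq, rec))
    allt = pd.concat(tables)
    return (
        allt.groupby(["structure", "frames"], as_index=False)[["HD", "ASSD"]]
        .mean()
        .pivot(index="structure", columns="frames", values=["HD", "ASSD"])
    )


# ---------------------------------------------------------------------------
# distribution similarity
# ---------------------------------------------------------------------------


def kl_wd(real: np.ndarray, synth: np.ndarray) -> Tuple[float, float]:
    """Histogram KL(real || synth) on shared Freedman-Diaconis bins (with
    additive smoothing 1e-8) and the 1-D empirical Wasserstein distance."""
    real = np.asarray(real, dtype=float)
    synth = np.asarray(synth, dtype=float)
    pooled = np.concatenate([real, synth])
    edges = np.histogram_bin_edges(pooled, bins="fd")
    if len(edges) < 3:
        edges = np.histogram_bin_edges(pooled, bins=10)
    p = np.histogram(real, bins=edges)[0].astype(float) + 1e-8
    q = np.histogram(synth, bins=edges)[0].astype(float) + 1e-8
    p /= p.sum()
    q /= q.sum()
    kl = float(np.sum(p * np.log(p / q)))
    wd = float(stats.wasserstein_distance(real, synth))
    return kl, wd


def _strata(df: pd.DataFrame, by: Optional[str]) -> List[np.ndarray]:
    if by is None:
        return [np.ones(len(df), dtype=bool)]
    if by == "sex":
        return [(df["sex"] == s).to_numpy() for s in (0, 1)]
    if by == "age":
        decades = (df["age"] // 10).astype(int)
        return [(decades == d).to_numpy() for d in sorted(decades.unique())]
    raise ValueError(f"unsupported conditioning variable {by!r}")


def phenotype_distribution_similarity(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    by: Optional[str] = None,
    phenotypes: Sequence[str] = PHENOTYPE_NAMES,
    min_samples: int = 20,
) -> pd.DataFrame:
    """Per-phenotype (KL, WD) between real and synthetic samples.

    With ``by`` in {"age", "sex"} the metrics are computed within strata
    (decade bins for age) and averaged; strata with fewer than
    ``min_samples`` on either side are skipped with a warning.
    """
    rows = []
    real_strata = _strata(real, by)
    synth_strata = _strata(synth, by)
    for name in phenotypes:
        kls, wds = [], []
        for mr, ms in zip(real_strata, synth_strata):
            if mr.sum() < min_samples or ms.sum() < min_samples:
                warnings.warn(f"skipping under-populated stratum for {name}")
                continue
            kl, wd = kl_wd(real.loc[mr, name].to_numpy(), synth.loc[ms, name].to_numpy())
            kls.append(kl)
            wds.append(wd)
        if not kls:
            raise ValueError(f"no stratum with >= {min_samples} samples for {name}")
        rows.append({"phenotype": name, "KL": np.mean(kls), "WD": np.mean(wds)})
    return pd.DataFrame(rows).set_index("phenotype")


def phenotype_table(sequences: Iterable[MeshSequence]) -> pd.DataFrame:
    """Measured phenotypes plus conditions for a collection of sequences."""
    rows = []
    for seq in sequences:
        d = compute_phenotypes(seq).to_dict()
        d.update(
            subject_id=seq.subject_id,
            age=seq.condition.age,
            sex=seq.condition.sex,
            weight=seq.condition.weight,
            height=seq.condition.height,
        )
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent delta
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeltaRecord:
    """Personalized normative deviation of one subject."""

    subject_id: str
    delta_z: float
    n_reference_samples: int
    seed: int


def latent_delta(
    state: ModelState,
    seq: MeshSequence,
    n: int = 100,
    seed: int = 0,
    chunk: int = 25,
) -> DeltaRecord:
    """Latent delta: ||z_real - mean_i z_synth_i||_2 over ``n`` synthetic
    sequences generated from the subject's own conditions (z_a ~ N(0, I)),
    each re-encoded through the mesh and transformer encoders."""
    state.check_topology(seq)
    z_real = latent_vector(seq, state)
    rng = np.random.default_rng(seed)
    z_synths = np.empty((n, state.config.d_latent))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        z_a = rng.standard_normal((m, state.config.d_latent))
        verts = decode_samples(state, seq.condition, z_a, T=seq.T)
        z_synths[done : done + m] = batch_latent_vectors(state, verts, seq.condition)
        done += m
    delta = float(np.linalg.norm(z_real - z_synths.mean(axis=0)))
    return DeltaRecord(
        subject_id=seq.subject_id, delta_z=delta, n_reference_samples=n, seed=seed
    )


# ---------------------------------------------------------------------------
# classification harness
# ---------------------------------------------------------------------------

CLASSIFIERS = ("adaboost", "lda", "svm")


def _make_classifier(kind: str, seed: int):
    if kind == "adaboost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "svm":
        return SVC(kernel="linear", random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def classification_harness(
    features,
    labels,
    classifiers: Sequence[str] = CLASSIFIERS,
    n_splits: int = 5,
    seed: int = 0,
    test_size: float = 0.3,
) -> pd.DataFrame:
    """AUC of each classifier averaged over seeded random train/test splits.

    ``features`` is a DataFrame/array, or a dict of named feature sets;
    returns a table indexed by (feature_set, classifier) with mean and SD of
    the AUC across splits.
    """
    if not isinstance(features, dict):
        features = {"features": features}
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    rows = []
    for set_name, X in features.items():
        X = np.asarray(X, dtype=float)
        for kind in classifiers:
            aucs = []
            for split in range(n_splits):
                Xtr, Xte, ytr, yte = train_test_split(
                    X, y, test_size=test_size, random_state=seed + split, stratify=y
                )
                scaler = StandardScaler().fit(Xtr)
                clf = _make_classifier(kind, seed + split)
                clf.fit(scaler.transform(Xtr), ytr)
                score = (
                    clf.decision_function(scaler.transform(Xte))
                    if hasattr(clf, "decision_function")
                    else clf.predict_proba(scaler.transform(Xte))[:, 1]
                )
                aucs.append(roc_auc_score(yte, score))
            rows.append(
                {
                    "feature_set": set_name,
                    "classifier": kind,
                    "AUC": float(np.mean(aucs)),
                    "AUC_sd": float(np.std(aucs)),
                }
            )
    return pd.DataFrame(rows).set_index(["feature_set", "classifier"])


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


def _logistic_score_test(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Score test for a single standardized covariate in a logistic model
    with intercept: U = sum x (y - ybar), Var(U) = ybar (1 - ybar) sum
    (x - xbar)^2; U^2 / Var ~ chi2(1) under the null."""
    ybar = y.mean()
    xc = x - x.mean()
    u = float(np.sum(x * (y - ybar)))
    var = float(ybar * (1.0 - ybar) * np.sum(xc**2))
    if var <= 0:
        return 0.0, 1.0
    chi2 = u**2 / var
    return np.sign(u) * np.sqrt(chi2), float(stats.chi2.sf(chi2, df=1))


def association_scan(
    deltas: pd.DataFrame,
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan binary outcome columns for association with the latent delta.

    ``deltas`` must have a ``delta_z`` column aligned with ``outcomes``
    rows. Each outcome gets a logistic score test on the standardized delta;
    Bonferroni significance uses the number of outcomes actually tested.
    Constant outcome columns are skipped with a warning.
    """
    x = np.asarray(deltas["delta_z"], dtype=float)
    x = (x - x.mean()) / (x.std() + 1e-12)
    rows = []
    for col in outcomes.columns:
        y = np.asarray(outcomes[col], dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError(f"outcome {col!r} is not binary")
        if len(np.unique(y)) < 2:
            warnings.warn(f"skipping constant outcome {col!r}")
            continue
        zstat, p = _logistic_score_test(x, y)
        rows.append({"outcome": col, "direction": int(np.sign(zstat)), "z": zstat, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no testable outcome column")
    n_tested = len(df)
    df["p_bonferroni"] = np.minimum(df["p"] * n_tested, 1.0)
    df["significant"] = df["p"] < alpha / n_tested
    df["family_size"] = n_tested
    return df.set_index("outcome")
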