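"""Evaluation tables, distribution similarity, latent delta and the
classification/association harnesses."""

import numpy as np
import pandas as pd
import pytest

from cardiomesh.evaluation import (
    association_scan,
    classification_harness,
    evaluate_reconstruction,
    kl_wd,
    latent_delta,
    phenotype_distribution_similarity,
    phenotype_table,
)
from cardiomesh.meshes import Condition
from cardiomesh.model import ModelConfig, init_state, decode_samples, batch_latent_vectors, latent_vector
from cardiomesh.population import PopulationSpec, generate_sequence

from conftest import cube_sequence


SPEC = PopulationSpec(T=5, vertices_per_part=42, seed=0)
COND = Condition(age=60, sex=0, weight=70, height=162)


@pytest.fixture(scope="module")
def small_state():
    seq = generate_sequence(COND, SPEC, seed=1)
    return init_state(ModelConfig(T=5), seq.frames[0], seed=0), seq


# ---------------------------------------------------------------------------
# reconstruction table
# ---------------------------------------------------------------------------


def test_eval_table_identity_is_zero(small_state):
    state, seq = small_state
    table = evaluate_reconstruction(state, [seq], reconstructions=[seq])
    assert (table.to_numpy() == 0).all()


def test_eval_table_known_translation():
    seq = cube_sequence([120.0, 120.0, 120.0])
    rec = cube_sequence([120.0, 120.0, 120.0])
    for f in rec.frames:
        f.vertices = f.vertices + np.array([3.0, 4.0, 0.0])  # distance 5 everywhere
    table = evaluate_reconstruction(None, [seq], reconstructions=[rec])
    np.testing.assert_allclose(table.to_numpy(), 5.0, atol=1e-12)
    # the "mean" row equals the average of the per-structure rows
    np.testing.assert_allclose(
        table.loc["mean"].to_numpy(),
        table.loc[["LV", "MYO", "RV"]].to_numpy().mean(axis=0),
        atol=1e-12,
    )


# ---------------------------------------------------------------------------
# KL / Wasserstein
# ---------------------------------------------------------------------------


def test_kl_wd_identity_and_point_masses():
    x = np.random.default_rng(0).normal(size=500)
    kl, wd = kl_wd(x, x)
    assert kl == pytest.approx(0.0, abs=1e-9)
    assert wd == 0.0
    _, wd01 = kl_wd(np.zeros(50), np.ones(50))
    assert wd01 == pytest.approx(1.0, abs=1e-12)


def test_wd_recovers_gaussian_mean_shift():
    rng = np.random.default_rng(1)
    a = rng.normal(2.0, 1.0, size=100000)
    b = rng.normal(5.0, 1.0, size=100000)
    _, wd = kl_wd(a, b)
    assert wd == pytest.approx(3.0, rel=0.02)
    kl_ab, _ = kl_wd(a, b)
    assert kl_ab > 0


def test_wd_triangle_inequality_spot_check():
    rng = np.random.default_rng(2)
    a, b, c = (rng.normal(m, 1.0, size=2000) for m in (0.0, 1.5, 4.0))
    wab = kl_wd(a, b)[1]
    wbc = kl_wd(b, c)[1]
    wac = kl_wd(a, c)[1]
    assert wac <= wab + wbc + 1e-9


def test_similarity_stratified_and_min_samples():
    rng = np.random.default_rng(3)
    n = 200
    real = pd.DataFrame(
        {
            "LVEDV": rng.normal(140, 20, n),
            "age": rng.uniform(45, 75, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    synth = real.copy()
    table = phenotype_distribution_similarity(real, synth, by="age", phenotypes=["LVEDV"])
    assert table.loc["LVEDV", "KL"] == pytest.approx(0.0, abs=1e-9)
    assert table.loc["LVEDV", "WD"] == 0.0
    # under-populated strata are skipped, not fatal, as long as one remains
    small = real.iloc[:30].copy()
    small["age"] = 50.0
    with pytest.warns(UserWarning):
        phenotype_distribution_similarity(
            pd.concat([small, small.assign(age=95.0).iloc[:5]], ignore_index=True),
            pd.concat([small, small.assign(age=95.0).iloc[:5]], ignore_index=True),
            by="age",
            phenotypes=["LVEDV"],
        )


# ---------------------------------------------------------------------------
# latent delta
# ---------------------------------------------------------------------------


def test_latent_delta_n1_is_plain_distance(small_state):
    state, seq = small_state
    rec = latent_delta(state, seq, n=1, seed=5)
    rng = np.random.default_rng(5)
    z_a = rng.standard_normal((1, 64))
    verts = decode_samples(state, seq.condition, z_a, T=seq.T)
    z_synth = batch_latent_vectors(state, verts, seq.condition)[0]
    expected = float(np.linalg.norm(latent_vector(seq, state) - z_synth))
    assert rec.delta_z == pytest.approx(expected, rel=1e-6)
    assert rec.delta_z >= 0
    assert rec.n_reference_samples == 1


def test_latent_delta_defaults():
    import inspect

    assert inspect.signature(latent_delta).parameters["n"].default == 100


# ---------------------------------------------------------------------------
# classification harness
# ---------------------------------------------------------------------------


def test_classification_perfectly_separable():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 3))
    y = (x[:, 0] > 0).astype(int)
    table = classification_harness(x, y, n_splits=3, seed=0)
    assert (table["AUC"] > 0.95).all()
    assert (table.loc[("features", "lda"), "AUC"] > 0.98).all()


def test_classification_null_labels():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(600, 5))
    y = rng.integers(0, 2, size=600)  # independent of features
    table = classification_harness(x, y, n_splits=5, seed=0)
    assert np.abs(table["AUC"] - 0.5).max() < 0.07


def test_classification_harness_contract():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(60, 2))
    with pytest.raises(ValueError):
        classification_harness(x, np.zeros(60, dtype=int))
    table = classification_harness(
        {"a": x, "b": x[:, :1]}, (x[:, 0] > 0).astype(int), n_splits=2, seed=1
    )
    assert set(table.index.get_level_values("feature_set")) == {"a", "b"}
    assert set(table.index.get_level_values("classifier")) == {"adaboost", "lda", "svm"}


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


def test_association_scan_detects_constructed_signal():
    rng = np.random.default_rng(3)
    deltas = pd.DataFrame({"delta_z": rng.gamma(2.0, 1.0, size=300)})
    outcomes = pd.DataFrame({"above_median": (deltas["delta_z"] > deltas["delta_z"].median()).astype(int)})
    table = association_scan(deltas, outcomes)
    assert table.loc["above_median", "significant"]
    assert table.loc["above_median", "direction"] == 1
    assert table.loc["above_median", "family_size"] == 1


def test_association_scan_single_outcome_threshold_and_constant_column():
    rng = np.random.default_rng(4)
    deltas = pd.DataFrame({"delta_z": rng.normal(size=100)})
    outcomes = pd.DataFrame(
        {"random": rng.integers(0, 2, 100), "constant": np.zeros(100, dtype=int)}
    )
    with pytest.warns(UserWarning, match="constant"):
        table = association_scan(deltas, outcomes)
    assert list(table.index) == ["random"]
    # with one tested outcome the Bonferroni threshold equals raw alpha
    assert table["family_size"].iloc[0] == 1
    assert bool(table["significant"].iloc[0]) == bool(table["p"].iloc[0] < 0.05)
    with pytest.raises(ValueError):
        association_scan(deltas, pd.DataFrame({"bad": rng.normal(size=100)}))


def test_phenotype_table_columns(small_state):
    _, seq = small_state
    df = phenotype_table([seq])
    for col in ("LVEDV", "LVEF", "age", "sex", "subject_id"):
        assert col in df.columns
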