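"""Loss functions and the optimisation loop.

The total loss is ``L = L_R + L_KL + lambda_s * L_S``:

* ``L_R`` — mean over frames of the symmetric Chamfer distance between
  predicted and target vertex sets;
* ``L_KL`` — beta-weighted KL divergence between the encoder's diagonal
  Gaussian and the standard normal prior;
* ``L_S`` — mean over frames of the Laplacian smoothness of the predicted
  mesh (norm of the mean neighbour-offset vector, averaged over vertices).

Training uses Adam with a fixed learning rate and a batch of one sequence,
fully seeded (parameter init, data order, epsilon draws).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .meshes import (
    MeshSequence,
    assd,
    chamfer_distance,
    laplacian_smoothness,
    neighbour_operator,
    read_mesh_sequence,
)
from .model import (
    GaussianLatent,
    ModelConfig,
    ModelState,
    forward_reconstruct_t,
    init_state,
    save_checkpoint,
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; the reference configuration uses beta=0.01,
    lambda_s=1, lr=1e-4 and 300 epochs — the desk default trains 50."""

    beta: float = 0.01
    lambda_s: float = 1.0
    learning_rate: float = 1e-4
    epochs: int = 50
    seed: int = 0
    grad_clip: Optional[float] = None
    checkpoint_every: int = 0  # epochs; 0 = only final
    val_every: int = 0  # epochs between validation ASSD evaluations; 0 = never
    val_subjects: int = 5

    def __post_init__(self) -> None:
        if self.beta < 0 or self.lambda_s < 0:
            raise ValueError("beta and lambda_s must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


@dataclass
class LossReport:
    """Per-step loss components with the identity
    L_total = L_R + L_KL + lambda_s * L_S."""

    steps: pd.DataFrame
    lambda_s: float

    def epoch_summary(self) -> pd.DataFrame:
        return self.steps.groupby("epoch")[["L_R", "L_KL", "L_S", "L_total"]].mean()

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# differentiable losses
# ---------------------------------------------------------------------------


def chamfer_loss_t(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over frames of the Chamfer distance (differentiable w.r.t. the
    prediction; nearest neighbours fixed from current values)."""
    T = target.shape[0]
    terms = []
    for t in range(T):
        p = pred[t]
        tgt = target[t]
        idx_pt = cKDTree(tgt).query(p.data)[1]
        idx_tp = cKDTree(p.data).query(tgt)[1]
        d_pt = ad.norm_rows(p - Tensor(tgt[idx_pt].astype(p.data.dtype))).mean()
        d_tp = ad.norm_rows(p[idx_tp] - Tensor(tgt.astype(p.data.dtype))).mean()
        terms.append(d_pt + d_tp)
    total = terms[0]
    for term in terms[1:]:
        total = total + term
    return total / float(T)


def kl_loss_t(mu: Tensor, log_sigma: Tensor, beta: float) -> Tensor:
    """beta * KL(N(mu, diag(sigma^2)) || N(0, I)), sigma = exp(log_sigma)."""
    var = (log_sigma * 2.0).exp()
    return (((mu * mu) + var - 1.0 - log_sigma * 2.0).sum()) * (0.5 * beta)


def smooth_loss_t(pred: Tensor, neighbour_op: sparse.csr_matrix) -> Tensor:
    """Mean over frames and vertices of the mean neighbour-offset norm."""
    T, V, _ = pred.shape
    flat = pred.reshape(T * V, 3)
    offsets = ad.spmm(neighbour_op, flat) - flat
    return ad.norm_rows(offsets).mean()


# ---------------------------------------------------------------------------
# public (non-differentiable) loss API mirroring the formulas
# ---------------------------------------------------------------------------


def loss_reconstruction(pred: MeshSequence, target: MeshSequence) -> float:
    """Mean over frames of the symmetric Chamfer distance (mm)."""
    if pred.T != target.T:
        raise ValueError("sequences differ in length")
    return float(
        np.mean(
            [
                chamfer_distance(p.vertices, t.vertices)
                for p, t in zip(pred.frames, target.frames)
            ]
        )
    )


def loss_kl(g: GaussianLatent, beta: float) -> float:
    """Closed-form KL of the diagonal Gaussian against N(0, I), times beta."""
    var = np.exp(2.0 * g.log_sigma)
    return float(0.5 * beta * np.sum(g.mu**2 + var - 1.0 - 2.0 * g.log_sigma))


def loss_smooth(pred: MeshSequence) -> float:
    """Mean over frames of the Laplacian smoothness (mm)."""
    edges = pred.frames[0].edges()
    return float(np.mean([laplacian_smoothness(f.vertices, edges) for f in pred.frames]))


def total_loss(l_r: float, l_kl: float, l_s: float, cfg: TrainConfig) -> float:
    """Weighted sum L_R + L_KL + lambda_s * L_S."""
    return float(l_r + l_kl + cfg.lambda_s * l_s)


# ---------------------------------------------------------------------------
# dataset access
# ---------------------------------------------------------------------------


def load_manifest(dataset) -> dict:
    """Accept a manifest dict, a dataset directory, or a splits.json path."""
    if isinstance(dataset, dict):
        return dataset
    p = Path(dataset)
    if p.is_dir():
        p = p / "splits.json"
    return json.loads(p.read_text())


def load_split(manifest: dict, split: str) -> List[MeshSequence]:
    root = Path(manifest["root"])
    return [read_mesh_sequence(root / sid) for sid in manifest["splits"][split]]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _mean_assd(state: ModelState, sequences: Sequence[MeshSequence]) -> float:
    from .model import reconstruct  # local import to avoid cycle at module load

    vals = []
    for seq in sequences:
        rec = reconstruct(seq, state)
        vals.append(
            np.mean(
                [assd(r.vertices, s.vertices) for r, s in zip(rec.frames, seq.frames)]
            )
        )
    return float(np.mean(vals))


def train(
    dataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    out_dir=None,
    sequences: Optional[List[MeshSequence]] = None,
    val_sequences: Optional[List[MeshSequence]] = None,
) -> Tuple[ModelState, LossReport]:
    """Train on the healthy training split of a dataset manifest.

    Returns the trained state and the per-step loss report. ``sequences``
    may be passed directly (bypassing disk) for testing; otherwise the
    manifest's train split is read. Raises :class:`TrainingDiverged` on a
    non-finite loss.
    """
    manifest = load_manifest(dataset) if sequences is None else None
    if sequences is None:
        labels = {s["subject_id"]: s["label"] for s in manifest.get("subjects", [])}
        bad = [sid for sid in manifest["splits"]["train"] if labels.get(sid, "healthy") != "healthy"]
        if bad:
            raise ValueError(f"training split must be healthy-only; found {bad[:3]}")
        sequences = load_split(manifest, "train")
        if val_sequences is None and manifest["splits"].get("val"):
            val_sequences = load_split(manifest, "val")
    if not sequences:
        raise ValueError("empty training split")

    template = sequences[0].frames[0]
    conds = np.array(
        [[s.condition.age, s.condition.weight, s.condition.height] for s in sequences]
    )
    cond_mean = conds.mean(axis=0)
    cond_sd = np.maximum(conds.std(axis=0), 1e-3)
    state = init_state(
        model_cfg, template, cond_mean=cond_mean, cond_sd=cond_sd, seed=train_cfg.seed
    )
    n_op = neighbour_operator(template.edges(), template.n_vertices)
    n_op_T = sparse.kron(
        sparse.identity(sequences[0].T, format="csr"), n_op, format="csr"
    ).astype(state.dtype)

    opt = Adam(state.params, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)
    vertex_arrays = [s.vertex_array() for s in sequences]

    rows: List[dict] = []
    step = 0
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(sequences))
        for i in order:
            seq = sequences[i]
            eps = rng.standard_normal(model_cfg.d_latent)
            pred, mu, log_sigma = forward_reconstruct_t(
                state, vertex_arrays[i], seq.condition, epsilon=eps, train=True, rng=rng
            )
            l_r = chamfer_loss_t(pred, vertex_arrays[i])
            l_kl = kl_loss_t(mu, log_sigma, train_cfg.beta)
            l_s = smooth_loss_t(pred, n_op_T)
            loss = l_r + l_kl + l_s * train_cfg.lambda_s
            value = float(loss.data)
            if not np.isfinite(value):
                report = LossReport(pd.DataFrame(rows), train_cfg.lambda_s)
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {step}", report.steps
                )
            opt.zero_grad()
            loss.backward()
            opt.step(grad_clip=train_cfg.grad_clip)
            rows.append(
                {
                    "epoch": epoch,
                    "step": step,
                    "subject": seq.subject_id,
                    "L_R": float(l_r.data),
                    "L_KL": float(l_kl.data),
                    "L_S": float(l_s.data),
                    "L_total": value,
                }
            )
            step += 1
        if (
            train_cfg.val_every
            and val_sequences
            and (epoch + 1) % train_cfg.val_every == 0
        ):
            v = _mean_assd(state, val_sequences[: train_cfg.val_subjects])
            rows[-1]["val_ASSD"] = v
        if (
            out is not None
            and train_cfg.checkpoint_every
            and (epoch + 1) % train_cfg.checkpoint_every == 0
        ):
            save_checkpoint(state, out / f"checkpoint_epoch{epoch + 1:04d}.npz")

    columns = ["epoch", "step", "subject", "L_R", "L_KL", "L_S", "L_total"]
    report = LossReport(
        pd.DataFrame(rows, columns=columns + (["val_ASSD"] if any("val_ASSD" in r for r in rows) else [])),
        train_cfg.lambda_s,
    )
    if out is not None:
        save_checkpoint(state, out / "checkpoint_final.npz")
        report.to_csv(out / "training_log.csv")
    return state, report
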