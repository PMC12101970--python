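"""Conditional spatio-temporal VAE over fixed-topology cardiac mesh sequences.

Architecture
------------
* condition encoder: MLP mapping (age, weight, height z-scored; sex one-hot)
  to a 32-d condition latent ``z_c``;
* mesh encoder: 3 graph-convolution layers (symmetric-normalised adjacency
  with self-loops over the template edge graph) on vertex coordinates,
  mean-pooled over vertices, then one FC layer to a 64-d per-frame latent;
* temporal transformer encoder: the T frame latents plus two learnable
  distribution-parameter tokens, each concatenated with ``z_c`` (token width
  96), pass through pre-norm self-attention blocks; the two token outputs
  parameterise a diagonal Gaussian (mu, log_sigma) over the 64-d sequence
  latent ``z_a``;
* reparameterization: ``z_a = mu + eps * exp(log_sigma)``;
* temporal transformer decoder: sinusoidal positional encodings of the T
  frame indices act as queries, cross-attending to the single memory token
  ``[z_a; z_c]``, producing T per-frame latents;
* mesh decoder: five FC layers from each frame latent to V x 3 vertex
  coordinates; the final bias is initialised to the template geometry so an
  untrained model outputs a plausible heart.

All forward paths run on the numpy autodiff engine in
:mod:`cardiomesh.autodiff`; inference-only entry points disable the tape.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .meshes import Condition, LabelledMesh, MeshSequence

#: vertex coordinates are divided by this (mm) before entering the encoder
COORD_SCALE = 50.0

CHECKPOINT_FORMAT = "cardiomesh-checkpoint-1"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults follow the reference configuration
    (latent 64, condition 32, 2 transformer layers, 4 heads, FF 1024,
    dropout 0.1) at desk-scale T."""

    d_latent: int = 64
    d_condition: int = 32
    gcn_hidden: Tuple[int, ...] = (64, 64, 64)
    decoder_widths: Tuple[int, ...] = (96, 256, 512, 1024)
    n_transformer_layers: int = 2
    n_heads: int = 4
    d_ff: int = 1024
    dropout: float = 0.1
    T: int = 20
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.d_latent <= 0 or self.d_condition <= 0:
            raise ValueError("latent dimensions must be positive")
        if (self.d_latent + self.d_condition) % self.n_heads != 0:
            raise ValueError("n_heads must divide the token width")

    @property
    def d_token(self) -> int:
        return self.d_latent + self.d_condition


# ---------------------------------------------------------------------------
# latent containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionLatent:
    z_c: np.ndarray  # (32,)


@dataclass(frozen=True)
class FrameLatents:
    z: np.ndarray  # (T, 64)


@dataclass(frozen=True)
class GaussianLatent:
    """Diagonal Gaussian over the sequence latent.

    ``log_sigma`` stores the log of the per-dimension scale, so the
    distribution scale is ``exp(log_sigma)`` (variance ``exp(2 log_sigma)``).
    """

    mu: np.ndarray
    log_sigma: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.log_sigma))):
            raise ValueError("non-finite Gaussian latent")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma)


@dataclass(frozen=True)
class SequenceLatent:
    z_a: np.ndarray
    epsilon: np.ndarray


# ---------------------------------------------------------------------------
# parameter shapes / init
# ---------------------------------------------------------------------------


def _param_shapes(cfg: ModelConfig, n_vertices: int) -> Dict[str, Tuple[int, ...]]:
    d, dc, dt = cfg.d_latent, cfg.d_condition, cfg.d_token
    shapes: Dict[str, Tuple[int, ...]] = {}

    def linear(name: str, fan_in: int, fan_out: int) -> None:
        shapes[f"{name}.W"] = (fan_in, fan_out)
        shapes[f"{name}.b"] = (fan_out,)

    # condition encoder MLP: 5 -> 64 -> d_condition
    linear("cond.0", 5, 64)
    linear("cond.1", 64, dc)
    # mesh encoder: GCN layers then one FC
    fan = 3
    for i, h in enumerate(cfg.gcn_hidden):
        linear(f"gcn.{i}", fan, h)
        fan = h
    linear("enc_fc", fan, d)
    # distribution parameter tokens
    shapes["token.mu"] = (1, d)
    shapes["token.sigma"] = (1, d)
    # transformer encoder / decoder blocks
    for side in ("enc", "dec"):
        for l in range(cfg.n_transformer_layers):
            p = f"{side}.{l}"
            shapes[f"{p}.ln1.g"] = (dt,)
            shapes[f"{p}.ln1.b"] = (dt,)
            for proj in ("q", "k", "v", "o"):
                linear(f"{p}.attn.{proj}", dt, dt)
            shapes[f"{p}.ln2.g"] = (dt,)
            shapes[f"{p}.ln2.b"] = (dt,)
            linear(f"{p}.ff.0", dt, cfg.d_ff)
            linear(f"{p}.ff.1", cfg.d_ff, dt)
        shapes[f"{side}.lnf.g"] = (dt,)
        shapes[f"{side}.lnf.b"] = (dt,)
    # encoder output heads (96 -> 64) for mu, sigma and frame tokens
    linear("head.mu", dt, d)
    linear("head.sigma", dt, d)
    linear("head.frame", dt, d)
    # decoder query embedding and output head
    linear("dec_qin", d, dt)
    linear("dec_out", dt, d)
    # mesh decoder: five FC layers d -> widths -> 3V
    fan = d
    for i, w in enumerate(cfg.decoder_widths):
        linear(f"mdec.{i}", fan, w)
        fan = w
    linear(f"mdec.{len(cfg.decoder_widths)}", fan, 3 * n_vertices)
    return shapes


def parameter_count(cfg: ModelConfig, n_vertices: int) -> int:
    """Total trainable parameter count for a given vertex budget."""
    return sum(int(np.prod(s)) for s in _param_shapes(cfg, n_vertices).values())


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------


def _gcn_adjacency(template: LabelledMesh) -> sparse.csr_matrix:
    """Symmetric-normalised adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    edges = template.edges()
    n = template.n_vertices
    i = np.concatenate([edges[:, 0], edges[:, 1], np.arange(n)])
    j = np.concatenate([edges[:, 1], edges[:, 0], np.arange(n)])
    a = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    dinv = sparse.diags(1.0 / np.sqrt(np.asarray(a.sum(axis=1)).ravel()))
    return (dinv @ a @ dinv).tocsr()


@dataclass
class ModelState:
    """All trainable parameters plus the fixed context they were built for:
    configuration, template topology, and condition normalisation."""

    params: Dict[str, Tensor]
    config: ModelConfig
    template: LabelledMesh
    cond_mean: np.ndarray  # (3,) mean of age, weight, height
    cond_sd: np.ndarray  # (3,)
    seed: int = 0
    _adj: sparse.csr_matrix = field(default=None, repr=False)
    _kron_cache: Dict[int, sparse.csr_matrix] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self._adj is None:
            self._adj = _gcn_adjacency(self.template).astype(self.dtype)

    @property
    def dtype(self):
        return np.dtype(self.config.dtype)

    @property
    def n_vertices(self) -> int:
        return self.template.n_vertices

    def frame_adjacency(self, T: int) -> sparse.csr_matrix:
        """Block-diagonal adjacency for T stacked frames."""
        if T not in self._kron_cache:
            self._kron_cache[T] = sparse.kron(
                sparse.identity(T, format="csr", dtype=self.dtype),
                self._adj,
                format="csr",
            ).astype(self.dtype)
        return self._kron_cache[T]

    def topology_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.template.faces.tobytes())
        h.update("".join(self.template.part_of_vertex.tolist()).encode())
        return h.hexdigest()[:16]

    def check_topology(self, seq: MeshSequence) -> None:
        f0 = seq.frames[0]
        if f0.vertices.shape != self.template.vertices.shape or not np.array_equal(
            f0.faces, self.template.faces
        ):
            raise ValueError("sequence topology does not match the model template")


def init_state(
    cfg: ModelConfig,
    template: LabelledMesh,
    cond_mean: Optional[np.ndarray] = None,
    cond_sd: Optional[np.ndarray] = None,
    seed: int = 0,
) -> ModelState:
    """Initialise parameters: He normal for weights feeding ReLU units
    (GCN, MLP hidden and mesh-decoder layers), fan-in uniform elsewhere,
    ones/zeros for LayerNorm, N(0, 0.02^2) for the distribution tokens, and
    the final mesh-decoder bias set to the template coordinates (so the
    untrained decoder outputs the template)."""
    dtype = np.dtype(cfg.dtype)
    rng = np.random.default_rng(seed)
    shapes = _param_shapes(cfg, template.n_vertices)
    n_dec = len(cfg.decoder_widths)
    relu_fed = (
        {f"gcn.{i}" for i in range(len(cfg.gcn_hidden))}
        | {f"mdec.{i}" for i in range(n_dec)}
        | {"cond.0"}
        | {f"{side}.{l}.ff.0" for side in ("enc", "dec") for l in range(cfg.n_transformer_layers)}
    )
    params: Dict[str, Tensor] = {}
    for name, shape in shapes.items():
        if name.startswith("token."):
            data = rng.normal(0.0, 0.02, size=shape)
        elif name.endswith(".g"):
            data = np.ones(shape)
        elif name.endswith(".b") and not name.split(".b")[0] + ".W" in shapes:
            data = np.zeros(shape)  # LayerNorm shift
        elif name.endswith(".W"):
            if name[:-2] in relu_fed:
                data = rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)
            else:
                bound = 1.0 / np.sqrt(shape[0])
                data = rng.uniform(-bound, bound, size=shape)
        else:  # linear bias
            fan_in = shapes[name[:-2] + ".W"][0]
            bound = 1.0 / np.sqrt(fan_in)
            data = rng.uniform(-bound, bound, size=shape)
        params[name] = ad.parameter(data, dtype=dtype)
    last = f"mdec.{len(cfg.decoder_widths)}.b"
    params[last] = ad.parameter(template.vertices.ravel(), dtype=dtype)
    # fallback normalisation covers a plausible adult population; training
    # replaces these with training-set statistics
    mean = np.array([60.0, 77.0, 169.0]) if cond_mean is None else np.asarray(cond_mean, dtype=float)
    sd = np.array([12.0, 14.0, 10.0]) if cond_sd is None else np.asarray(cond_sd, dtype=float)
    return ModelState(
        params=params, config=cfg, template=template, cond_mean=mean, cond_sd=sd, seed=seed
    )


# ---------------------------------------------------------------------------
# forward passes (Tensor-valued; used directly by training)
# ---------------------------------------------------------------------------


def _linear(state: ModelState, name: str, x: Tensor) -> Tensor:
    return x @ state.params[f"{name}.W"] + state.params[f"{name}.b"]


def _ln(state: ModelState, name: str, x: Tensor) -> Tensor:
    return ad.layer_norm(x, state.params[f"{name}.g"], state.params[f"{name}.b"])


def _broadcast_rows(t: Tensor, n: int, dtype) -> Tensor:
    return t + Tensor(np.zeros((n, t.shape[-1]), dtype=dtype))


def condition_features(state: ModelState, c: Condition) -> np.ndarray:
    """Normalised model inputs: z-scored age/weight/height plus sex one-hot."""
    cont = (np.array([c.age, c.weight, c.height]) - state.cond_mean) / state.cond_sd
    if np.any(np.abs(cont) > 10.0):
        raise ValueError("condition far outside the training distribution")
    return np.concatenate([cont, [1.0 - c.sex, float(c.sex)]]).astype(state.dtype)


def condition_encode_t(state: ModelState, c: Condition) -> Tensor:
    x = Tensor(condition_features(state, c)[None, :])
    h = _linear(state, "cond.0", x).relu()
    return _linear(state, "cond.1", h)  # (1, d_condition)


def mesh_encode_frames_t(state: ModelState, vertices: np.ndarray) -> Tensor:
    """Encode T frames of vertex coordinates to (T, d_latent) frame latents.

    The GCN sees displacements from the template (divided by the coordinate
    scale): the constant population shape carries no information, and using
    raw coordinates would leave the informative deviations orders of
    magnitude below the mean signal.
    """
    T, V, _ = vertices.shape
    adj = state.frame_adjacency(T)
    rel = (vertices - state.template.vertices) / COORD_SCALE
    h = Tensor(rel.reshape(T * V, 3).astype(state.dtype))
    for i in range(len(state.config.gcn_hidden)):
        h = _linear(state, f"gcn.{i}", ad.spmm(adj, h)).relu()
    pooled = h.reshape(T, V, h.shape[-1]).mean(axis=1)  # (T, d)
    return _linear(state, "enc_fc", pooled)


def _attention(
    state: ModelState,
    prefix: str,
    queries: Tensor,
    keys_values: Tensor,
) -> Tensor:
    cfg = state.config
    h, dt = cfg.n_heads, cfg.d_token
    dh = dt // h
    nq, nk = queries.shape[0], keys_values.shape[0]
    q = _linear(state, f"{prefix}.q", queries).reshape(nq, h, dh).transpose(1, 0, 2)
    k = _linear(state, f"{prefix}.k", keys_values).reshape(nk, h, dh).transpose(1, 0, 2)
    v = _linear(state, f"{prefix}.v", keys_values).reshape(nk, h, dh).transpose(1, 0, 2)
    scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
    attn = ad.softmax(scores, axis=-1)
    out = (attn @ v).transpose(1, 0, 2).reshape(nq, dt)
    return _linear(state, f"{prefix}.o", out)


def _transformer_stack(
    state: ModelState,
    side: str,
    x: Tensor,
    memory: Optional[Tensor],
    train: bool,
    rng: Optional[np.random.Generator],
) -> Tensor:
    """Pre-norm blocks with residuals; self-attention when ``memory`` is
    None, cross-attention to ``memory`` otherwise; final LayerNorm."""
    cfg = state.config
    rate = cfg.dropout if train else 0.0
    for l in range(cfg.n_transformer_layers):
        p = f"{side}.{l}"
        normed = _ln(state, f"{p}.ln1", x)
        kv = normed if memory is None else memory
        a = _attention(state, f"{p}.attn", normed, kv)
        if rate > 0:
            a = ad.dropout(a, rate, rng)
        x = x + a
        f = _linear(state, f"{p}.ff.1", _linear(state, f"{p}.ff.0", _ln(state, f"{p}.ln2", x)).relu())
        if rate > 0:
            f = ad.dropout(f, rate, rng)
        x = x + f
    return _ln(state, f"{side}.lnf", x)


def temporal_encode_t(
    state: ModelState,
    frame_latents: Tensor,
    z_c: Tensor,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Tensor, Tensor, Tensor]:
    """Returns (mu, log_sigma, frame_outputs) from the transformer encoder.

    Sinusoidal temporal encodings are added to the frame tokens (not the
    distribution tokens) so self-attention can see frame order; without
    them the posterior would be invariant to temporal shuffling.
    """
    T = frame_latents.shape[0]
    pe = Tensor(positional_encoding_matrix(T, state.config.d_latent).astype(state.dtype))
    tokens = ad.concatenate(
        [state.params["token.mu"], state.params["token.sigma"], frame_latents + pe],
        axis=0,
    )  # (T+2, d_latent)
    z = ad.concatenate(
        [tokens, _broadcast_rows(z_c, T + 2, state.dtype)], axis=1
    )  # (T+2, d_token)
    z = _transformer_stack(state, "enc", z, None, train, rng)
    mu = _linear(state, "head.mu", z[0:1]).reshape(-1)
    log_sigma = _linear(state, "head.sigma", z[1:2]).reshape(-1)
    frame_out = _linear(state, "head.frame", z[2:])
    return mu, log_sigma, frame_out


def positional_encoding(t: int, d: int) -> np.ndarray:
    """Sinusoidal temporal encoding: sin at even indices, cos at odd, with
    wavelength 10000^(2k/d) at index pair k."""
    if t < 0 or d % 2 != 0:
        raise ValueError("t must be >= 0 and d even")
    k = np.arange(d // 2)
    freq = 1.0 / (10000.0 ** (2.0 * k / d))
    p = np.empty(d)
    p[0::2] = np.sin(t * freq)
    p[1::2] = np.cos(t * freq)
    return p


@lru_cache(maxsize=8)
def _pe_matrix_cached(T: int, d: int) -> np.ndarray:
    m = np.stack([positional_encoding(t, d) for t in range(T)])
    m.setflags(write=False)
    return m


def positional_encoding_matrix(T: int, d: int) -> np.ndarray:
    return _pe_matrix_cached(T, d)


def temporal_decode_t(
    state: ModelState,
    z_a: Tensor,
    z_c: Tensor,
    T: int,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """Cross-attention decoder: positional encodings query the single
    memory token [z_a; z_c]; returns (T, d_latent) frame latents."""
    pe = Tensor(positional_encoding_matrix(T, state.config.d_latent).astype(state.dtype))
    x = _linear(state, "dec_qin", pe)  # (T, d_token)
    memory = ad.concatenate([z_a, z_c], axis=1)  # (1, d_token)
    x = _transformer_stack(state, "dec", x, memory, train, rng)
    return _linear(state, "dec_out", x)


def mesh_decode_t(state: ModelState, frame_latents: Tensor) -> Tensor:
    """Five FC layers to (T, V, 3) coordinates in mm."""
    n_layers = len(state.config.decoder_widths) + 1
    h = frame_latents
    for i in range(n_layers - 1):
        h = _linear(state, f"mdec.{i}", h).relu()
    out = _linear(state, f"mdec.{n_layers - 1}", h)
    return out.reshape(out.shape[0], state.n_vertices, 3)


# numpy fast paths for the two heavy stages (inference only; the Tensor
# versions above remain the single source of truth for training gradients)


def _mesh_encode_frames_np(state: ModelState, vertices: np.ndarray) -> np.ndarray:
    n, V, _ = vertices.shape
    adj = state.frame_adjacency(n)
    rel = (vertices - state.template.vertices) / COORD_SCALE
    h = rel.reshape(n * V, 3).astype(state.dtype)
    for i in range(len(state.config.gcn_hidden)):
        h = adj @ h
        h = h @ state.params[f"gcn.{i}.W"].data
        h += state.params[f"gcn.{i}.b"].data
        np.maximum(h, 0.0, out=h)
    pooled = h.reshape(n, V, -1).mean(axis=1)
    out = pooled @ state.params["enc_fc.W"].data
    out += state.params["enc_fc.b"].data
    return out


def _mesh_decode_np(state: ModelState, frame_latents: np.ndarray) -> np.ndarray:
    n_layers = len(state.config.decoder_widths) + 1
    h = frame_latents.astype(state.dtype)
    for i in range(n_layers - 1):
        h = h @ state.params[f"mdec.{i}.W"].data
        h += state.params[f"mdec.{i}.b"].data
        np.maximum(h, 0.0, out=h)
    out = h @ state.params[f"mdec.{n_layers - 1}.W"].data
    out += state.params[f"mdec.{n_layers - 1}.b"].data
    return out.reshape(h.shape[0], state.n_vertices, 3)


def forward_reconstruct_t(
    state: ModelState,
    vertices: np.ndarray,
    c: Condition,
    epsilon: Optional[np.ndarray] = None,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Tensor, Tensor, Tensor]:
    """Full pipeline on raw vertex arrays; returns (pred, mu, log_sigma)."""
    T = vertices.shape[0]
    z_c = condition_encode_t(state, c)
    fl = mesh_encode_frames_t(state, vertices)
    mu, log_sigma, _ = temporal_encode_t(state, fl, z_c, train, rng)
    if epsilon is None:
        z_a = mu.reshape(1, -1)
    else:
        eps = Tensor(np.asarray(epsilon, dtype=state.dtype))
        z_a = (mu + eps * log_sigma.exp()).reshape(1, -1)
    dec = temporal_decode_t(state, z_a, z_c, T, train, rng)
    return mesh_decode_t(state, dec), mu, log_sigma


# ---------------------------------------------------------------------------
# public inference API
# ---------------------------------------------------------------------------


def condition_encode(c: Condition, state: ModelState) -> ConditionLatent:
    """Deterministic 32-d embedding of the clinical conditions."""
    with no_grad():
        return ConditionLatent(z_c=condition_encode_t(state, c).data.reshape(-1).copy())


def mesh_encode(x_t: LabelledMesh, state: ModelState) -> np.ndarray:
    """64-d latent of a single frame (GCN + mean pool + FC)."""
    if x_t.vertices.shape != state.template.vertices.shape:
        raise ValueError("frame topology does not match the model template")
    with no_grad():
        return mesh_encode_frames_t(state, x_t.vertices[None]).data[0].copy()


def temporal_encode(
    frame_latents: FrameLatents, z_c: ConditionLatent, state: ModelState
) -> GaussianLatent:
    """Distribution-token outputs of the transformer encoder."""
    with no_grad():
        mu, log_sigma, _ = temporal_encode_t(
            state,
            Tensor(np.asarray(frame_latents.z, dtype=state.dtype)),
            Tensor(np.asarray(z_c.z_c, dtype=state.dtype)[None, :]),
        )
        return GaussianLatent(mu=mu.data.copy(), log_sigma=log_sigma.data.copy())


def reparameterize(
    g: GaussianLatent,
    epsilon: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> SequenceLatent:
    """z_a = mu + eps * exp(log_sigma), eps ~ N(0, I) unless given."""
    if epsilon is None:
        epsilon = np.random.default_rng(seed).standard_normal(len(g.mu))
    epsilon = np.asarray(epsilon, dtype=float)
    return SequenceLatent(z_a=g.mu + epsilon * np.exp(g.log_sigma), epsilon=epsilon)


def temporal_decode(
    z_a: SequenceLatent, z_c: ConditionLatent, T: int, state: ModelState
) -> FrameLatents:
    with no_grad():
        out = temporal_decode_t(
            state,
            Tensor(np.asarray(z_a.z_a, dtype=state.dtype)[None, :]),
            Tensor(np.asarray(z_c.z_c, dtype=state.dtype)[None, :]),
            T,
        )
        return FrameLatents(z=out.data.copy())


def mesh_decode(frame_latent: np.ndarray, state: ModelState) -> np.ndarray:
    """Decode one 64-d frame latent to V x 3 vertex coordinates (mm)."""
    with no_grad():
        out = mesh_decode_t(state, Tensor(np.asarray(frame_latent, dtype=state.dtype)[None, :]))
        return out.data[0].copy()


def _sequence_from_vertices(
    state: ModelState, vertices: np.ndarray, c: Condition, subject_id: str
) -> MeshSequence:
    tpl = state.template
    frames = [
        LabelledMesh(
            vertices=vertices[t],
            faces=tpl.faces,
            part_of_vertex=tpl.part_of_vertex,
            part_surfaces=tpl.part_surfaces,
        )
        for t in range(vertices.shape[0])
    ]
    return MeshSequence(frames=frames, condition=c, subject_id=subject_id)


def reconstruct(seq: MeshSequence, state: ModelState, epsilon: Optional[np.ndarray] = None) -> MeshSequence:
    """Encode and decode a sequence; evaluation mode uses the posterior mean
    (epsilon = 0)."""
    state.check_topology(seq)
    with no_grad():
        pred, _, _ = forward_reconstruct_t(state, seq.vertex_array(), seq.condition, epsilon)
        return _sequence_from_vertices(
            state, pred.data.astype(np.float64), seq.condition, f"{seq.subject_id}-recon"
        )


def decode_samples(
    state: ModelState, c: Condition, z_a: np.ndarray, T: Optional[int] = None
) -> np.ndarray:
    """Decode an (n, d_latent) batch of sequence latents to vertex arrays
    (n, T, V, 3) in one pass (frames of all samples stacked)."""
    T = state.config.T if T is None else T
    n = z_a.shape[0]
    with no_grad():
        z_c = condition_encode_t(state, c)
        fls = [
            temporal_decode_t(
                state, Tensor(z_a[i : i + 1].astype(state.dtype)), z_c, T
            ).data
            for i in range(n)
        ]
        out = _mesh_decode_np(state, np.concatenate(fls, axis=0))  # (n*T, V, 3)
        return out.reshape(n, T, state.n_vertices, 3).astype(np.float64)


def generate(
    c: Condition, n_samples: int, seed: int, state: ModelState, T: Optional[int] = None
) -> List[MeshSequence]:
    """Sample z_a ~ N(0, I) and decode condition-matched sequences."""
    rng = np.random.default_rng(seed)
    z_a = rng.standard_normal((n_samples, state.config.d_latent))
    verts = decode_samples(state, c, z_a, T)
    return [
        _sequence_from_vertices(state, verts[i], c, f"gen-{i:03d}")
        for i in range(n_samples)
    ]


def encode_vertex_array(state: ModelState, vertices: np.ndarray, c: Condition) -> np.ndarray:
    """Latent vector (64-d) of a raw T x V x 3 vertex array."""
    with no_grad():
        z_c = condition_encode_t(state, c)
        fl = mesh_encode_frames_t(state, vertices)
        _, _, frame_out = temporal_encode_t(state, fl, z_c)
        return frame_out.data.mean(axis=0).copy()


def batch_latent_vectors(state: ModelState, vertices: np.ndarray, c: Condition) -> np.ndarray:
    """Latent vectors (n, 64) for ``n`` same-condition sequences given as an
    (n, T, V, 3) array; the GCN runs once over all stacked frames."""
    n, T, V, _ = vertices.shape
    with no_grad():
        z_c = condition_encode_t(state, c)
        fl_all = _mesh_encode_frames_np(state, vertices.reshape(n * T, V, 3))
        out = np.empty((n, state.config.d_latent))
        for i in range(n):
            _, _, frame_out = temporal_encode_t(
                state, Tensor(fl_all[i * T : (i + 1) * T]), z_c
            )
            out[i] = frame_out.data.mean(axis=0)
        return out


def latent_vector(seq: MeshSequence, state: ModelState) -> np.ndarray:
    """Mean of the transformer-encoder frame-token outputs (before
    reparameterization) — a 64-d sequence descriptor."""
    state.check_topology(seq)
    return encode_vertex_array(state, seq.vertex_array(), seq.condition)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(state: ModelState, path) -> None:
    path = Path(path)
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": {k: getattr(state.config, k) for k in state.config.__dataclass_fields__},
        "cond_mean": state.cond_mean.tolist(),
        "cond_sd": state.cond_sd.tolist(),
        "seed": state.seed,
        "topology_hash": state.topology_hash(),
        "part_names": list(state.template.part_surfaces),
    }
    arrays = {f"param::{k}": p.data for k, p in state.params.items()}
    arrays["tpl::vertices"] = state.template.vertices
    arrays["tpl::faces"] = state.template.faces
    arrays["tpl::labels"] = state.template.part_of_vertex.astype("U3")
    for part, idx in state.template.part_surfaces.items():
        arrays[f"tplpart::{part}"] = idx
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format {meta.get('format')!r}")
        cfg_dict = dict(meta["config"])
        for key in ("gcn_hidden", "decoder_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        template = LabelledMesh(
            vertices=data["tpl::vertices"],
            faces=data["tpl::faces"],
            part_of_vertex=data["tpl::labels"],
            part_surfaces={p: data[f"tplpart::{p}"] for p in meta["part_names"]},
        )
        params = {
            k.split("::", 1)[1]: ad.parameter(data[k], dtype=np.dtype(cfg.dtype))
            for k in data.files
            if k.startswith("param::")
        }
    state = ModelState(
        params=params,
        config=cfg,
        template=template,
        cond_mean=np.array(meta["cond_mean"]),
        cond_sd=np.array(meta["cond_sd"]),
        seed=int(meta["seed"]),
    )
    if state.topology_hash() != meta["topology_hash"]:
        raise ValueError("checkpoint topology hash mismatch")
    return state
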