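"""The hybrid graph model: GCN levels with multi-modal drug branches,
drug-context injection, multi-head graph attention, and a pairwise MLP
decoder.

Forward pass, per level l = 0..n_levels-1:

    H ← ReLU(Â H W^l)                       graph convolution
    O ← fuse_k(ReLU(X_k P_k^l + b_k^l))     per-modality drug branches
    H ← [H ∥ O] (drug rows), [H ∥ 0] (disease rows)   context injection

then multi-head graph attention over the (un-normalized) adjacency's
neighborhoods,

    h_i' = ELU( (1/K) Σ_k Σ_{j∈N_i} α^k_ij W_g^k h_j ),
    α^k_ij = softmax_{j∈N_i} LeakyReLU(a_kᵀ [W_g^k h_i ∥ W_g^k h_j]),

and finally a 2-layer MLP scoring every (drug, disease) pair from the
concatenation of their embeddings, through a sigmoid.

Everything is float64 numpy via the package's autodiff module; all
randomness is seeded through the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import (
    Adam,  # re-exported for train_eval
    Tensor,
    concat_cols,
    dropout,
    masked_softmax_rows,
    pad_rows,
    repeat_rows,
    tile_rows,
)
from .data_io import DatasetBundle, MODALITY_CODES
from .hetgraph import HeteroGraph

__all__ = [
    "ModelConfig", "ModelParams", "ScoreMatrix", "init_params", "forward",
    "graph_conv", "modality_branch", "fuse_branches", "inject_context",
    "attention_coefficients", "graph_attention", "decode",
    "save_checkpoint", "load_checkpoint", "Adam",
]


@dataclass
class ModelConfig:
    """Hyperparameters.  Defaults follow the search grid where one exists
    (learning rate from {1e-4…1e-2}, embedding dimension from {64,128,256});
    iterations default to a desk-scale 500 with 10 000 available."""

    n_levels: int = 3
    embed_dim: int = 64
    n_heads: int = 4
    leaky_slope: float = 0.2
    delta: float = 0.5
    dropout: float = 0.1
    learning_rate: float = 0.005
    weight_decay: float = 0.005
    iterations: int = 500
    fusion: str = "weighted_sum"       # or "concat"
    modalities: tuple = ("t", "e", "p", "l")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.fusion not in ("weighted_sum", "concat"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.modalities = tuple(self.modalities)

    @property
    def modality_names(self) -> list[str]:
        return [MODALITY_CODES.get(m, m) for m in self.modalities]

    @property
    def fused_dim(self) -> int:
        if self.fusion == "concat":
            return self.embed_dim * len(self.modalities)
        return self.embed_dim


@dataclass
class ModelParams:
    """All learnable tensors, keyed by role."""

    tensors: dict[str, Tensor] = field(default_factory=dict)

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def __getitem__(self, key: str) -> Tensor:
        return self.tensors[key]

    def copy(self) -> "ModelParams":
        return ModelParams({
            k: Tensor(t.data.copy(), requires_grad=True)
            for k, t in self.tensors.items()
        })


@dataclass
class ScoreMatrix:
    """Predicted association scores in (0, 1), drugs × diseases."""

    values: np.ndarray
    drug_ids: list[str]
    disease_ids: list[str]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_params(config: ModelConfig, n_nodes: int,
                modality_dims: dict[str, int]) -> ModelParams:
    """Xavier-uniform initialization of every weight, seeded by the config.

    Level-l convolutions absorb the context-widened input (embed_dim +
    fused_dim) back down to embed_dim, so widths stay bounded across levels.
    """
    rng = np.random.default_rng(config.seed)
    d = config.embed_dim
    wide = d + config.fused_dim
    p: dict[str, Tensor] = {}
    for level in range(config.n_levels):
        fan_in = n_nodes if level == 0 else wide
        p[f"conv_W_{level}"] = _xavier(rng, fan_in, d)
        for name in config.modality_names:
            n_k = modality_dims[name]
            p[f"branch_P_{name}_{level}"] = _xavier(rng, n_k, d)
            p[f"branch_b_{name}_{level}"] = Tensor(
                np.zeros(d), requires_grad=True)
        if config.fusion == "weighted_sum":
            p[f"mix_{level}"] = Tensor(
                np.zeros(len(config.modalities)), requires_grad=True)
    for k in range(config.n_heads):
        p[f"att_W_{k}"] = _xavier(rng, wide, d)
        p[f"att_a_{k}"] = _xavier(rng, 2 * d, 1, shape=(2 * d,))
    p["dec_W1"] = _xavier(rng, 2 * d, d)
    p["dec_b1"] = Tensor(np.zeros(d), requires_grad=True)
    p["dec_w2"] = _xavier(rng, d, 1)
    p["dec_b2"] = Tensor(np.zeros(1), requires_grad=True)
    return ModelParams(p)


# ---------------------------------------------------------------------------
# components (Tensor core + numpy-facing wrappers)
# ---------------------------------------------------------------------------


def _graph_conv_t(h: Tensor, ahat: Tensor, w: Tensor) -> Tensor:
    return (ahat @ h @ w).relu()


def graph_conv(h: np.ndarray, ahat: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One propagation step ReLU(Â H W)."""
    for name, x in (("H", h), ("Ahat", ahat), ("W", w)):
        if not np.isfinite(x).all():
            raise ValueError(f"graph_conv: non-finite entries in {name}")
    return _graph_conv_t(Tensor(h), Tensor(ahat), Tensor(w)).data


def _modality_branch_t(x_k: Tensor, proj: Tensor, bias: Tensor) -> Tensor:
    return (x_k @ proj + bias).relu()


def modality_branch(x_k: np.ndarray, proj: np.ndarray,
                    bias: np.ndarray) -> np.ndarray:
    """Project one binary modality matrix to the embedding space: ReLU(XP + b)."""
    if x_k.shape[1] != proj.shape[0]:
        raise ValueError(
            f"modality_branch: {x_k.shape[1]} features vs projection "
            f"{proj.shape[0]} rows")
    return _modality_branch_t(Tensor(x_k), Tensor(proj), Tensor(bias)).data


def _fuse_t(projections: list[Tensor], mix_logits: Tensor | None,
            fusion: str) -> Tensor:
    if not projections:
        raise ValueError("fuse_branches: empty projection map")
    if fusion == "concat":
        return concat_cols(projections)
    z = mix_logits - Tensor(mix_logits.data.max())  # constant shift
    e = z.exp()
    w = e / e.sum()
    out = projections[0] * w.rows(0, 1)
    for i, pr in enumerate(projections[1:], start=1):
        out = out + pr * w.rows(i, i + 1)
    return out


def fuse_branches(projections: dict[str, np.ndarray],
                  mix_weights: np.ndarray | None = None,
                  fusion: str = "weighted_sum") -> np.ndarray:
    """Combine per-modality projections: softmax-weighted sum or concatenation."""
    keys = list(projections)
    if not keys:
        raise ValueError("fuse_branches: empty projection map")
    if fusion == "weighted_sum" and mix_weights is None:
        mix_weights = np.zeros(len(keys))
    mix = Tensor(mix_weights) if mix_weights is not None else None
    return _fuse_t([Tensor(projections[k]) for k in keys], mix, fusion).data


def _inject_t(h: Tensor, o: Tensor, c_count: int) -> Tensor:
    n = h.data.shape[0]
    if o.data.shape[0] != c_count:
        raise ValueError(
            f"inject_context: O has {o.data.shape[0]} rows, expected {c_count}")
    return concat_cols([h, pad_rows(o, n - c_count)])


def inject_context(h: np.ndarray, o: np.ndarray, c_count: int) -> np.ndarray:
    """Concatenate fused drug context onto drug rows; zero-pad disease rows."""
    return _inject_t(Tensor(h), Tensor(o), c_count).data


def _neighbor_mask(a: np.ndarray) -> np.ndarray:
    """Boolean neighborhoods from nonzero adjacency; self-loop for isolated rows."""
    mask = a != 0
    isolated = ~mask.any(axis=1)
    if isolated.any():
        mask = mask.copy()
        mask[np.flatnonzero(isolated), np.flatnonzero(isolated)] = True
    return mask


def _attention_logits_t(h: Tensor, w_g: Tensor, a_vec: Tensor,
                        leaky_slope: float) -> tuple[Tensor, Tensor]:
    """Pairwise logits e_ij = LeakyReLU(aᵀ[Wh_i ∥ Wh_j]) and f = HW."""
    d = w_g.data.shape[1]
    f = h @ w_g                                  # (n, d)
    u = f @ a_vec.rows(0, d).reshape(d, 1)       # aᵀ acting on Wh_i
    v = f @ a_vec.rows(d, 2 * d).reshape(d, 1)   # aᵀ acting on Wh_j
    logits = (u + v.T).leaky_relu(leaky_slope)
    return logits, f


def attention_coefficients(h: np.ndarray, a: np.ndarray, w_g: np.ndarray,
                           a_vec: np.ndarray,
                           leaky_slope: float = 0.2) -> np.ndarray:
    """Attention coefficients α_ij of one head; rows sum to 1 over N_i.

    Neighborhoods are the nonzero entries of ``a`` (symmetric); an isolated
    node falls back to a self-loop.
    """
    mask = _neighbor_mask(np.asarray(a))
    logits, _ = _attention_logits_t(Tensor(h), Tensor(w_g), Tensor(a_vec),
                                    leaky_slope)
    return masked_softmax_rows(logits, mask).data


def _graph_attention_t(h: Tensor, mask: np.ndarray,
                       heads: list[tuple[Tensor, Tensor]],
                       leaky_slope: float) -> Tensor:
    acc = None
    for w_g, a_vec in heads:
        logits, f = _attention_logits_t(h, w_g, a_vec, leaky_slope)
        alpha = masked_softmax_rows(logits, mask)
        out = alpha @ f
        acc = out if acc is None else acc + out
    return (acc * (1.0 / len(heads))).elu()


def graph_attention(h: np.ndarray, a: np.ndarray,
                    heads: list[tuple[np.ndarray, np.ndarray]],
                    leaky_slope: float = 0.2) -> np.ndarray:
    """Mean-aggregated K-head attention update with ELU output."""
    if len(heads) < 1:
        raise ValueError("graph_attention: need K >= 1 heads")
    mask = _neighbor_mask(np.asarray(a))
    heads_t = [(Tensor(w), Tensor(av)) for w, av in heads]
    return _graph_attention_t(Tensor(h), mask, heads_t, leaky_slope).data


def _decode_t(h_final: Tensor, c_count: int, w1: Tensor, b1: Tensor,
              w2: Tensor, b2: Tensor) -> tuple[Tensor, Tensor]:
    """Pairwise MLP logits and sigmoid scores, shape (|C|, |D|)."""
    n = h_final.data.shape[0]
    d_count = n - c_count
    hc = h_final.rows(0, c_count)
    hd = h_final.rows(c_count, n)
    pairs = concat_cols([repeat_rows(hc, d_count), tile_rows(hd, c_count)])
    hidden = (pairs @ w1 + b1).relu()
    logits = (hidden @ w2 + b2).reshape(c_count, d_count)
    return logits, logits.sigmoid()


def decode(h_final: np.ndarray, c_count: int, w1: np.ndarray, b1: np.ndarray,
           w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Score every (drug, disease) pair: sigmoid(MLP([h_i ∥ h_j]))."""
    _, scores = _decode_t(Tensor(h_final), c_count, Tensor(w1), Tensor(b1),
                          Tensor(w2), Tensor(b2))
    return scores.data


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------


def forward_tensors(params: ModelParams, config: ModelConfig,
                    ahat: np.ndarray, h0: np.ndarray, adjacency: np.ndarray,
                    modality_values: dict[str, np.ndarray], c_count: int,
                    train: bool = False,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Tensor, Tensor]:
    """Differentiable forward pass; returns (logits, scores) Tensors."""
    ahat_t = Tensor(ahat)
    h = Tensor(h0)
    for level in range(config.n_levels):
        h = _graph_conv_t(h, ahat_t, params[f"conv_W_{level}"])
        if train and config.dropout > 0:
            h = dropout(h, config.dropout, rng)
        projections = [
            _modality_branch_t(
                Tensor(modality_values[name]),
                params[f"branch_P_{name}_{level}"],
                params[f"branch_b_{name}_{level}"],
            )
            for name in config.modality_names
        ]
        mix = (params[f"mix_{level}"]
               if config.fusion == "weighted_sum" else None)
        o = _fuse_t(projections, mix, config.fusion)
        h = _inject_t(h, o, c_count)
    mask = _neighbor_mask(adjacency)
    heads = [(params[f"att_W_{k}"], params[f"att_a_{k}"])
             for k in range(config.n_heads)]
    h = _graph_attention_t(h, mask, heads, config.leaky_slope)
    if train and config.dropout > 0:
        h = dropout(h, config.dropout, rng)
    logits, scores = _decode_t(h, c_count, params["dec_W1"], params["dec_b1"],
                               params["dec_w2"], params["dec_b2"])
    return logits, scores


def forward(graph: HeteroGraph, bundle: DatasetBundle, params: ModelParams,
            config: ModelConfig) -> ScoreMatrix:
    """Deterministic end-to-end prediction on a built graph (eval mode)."""
    modality_values = {
        name: bundle.modalities[name].values.astype(np.float64)
        for name in config.modality_names
    }
    _, scores = forward_tensors(
        params, config, graph.normalized, graph.h0, graph.adjacency,
        modality_values, graph.n_drugs, train=False,
    )
    return ScoreMatrix(scores.data, list(graph.drug_ids),
                       list(graph.disease_ids))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(params: ModelParams, config: ModelConfig, path) -> None:
    """Single-file archive: every parameter tensor plus the JSON config."""
    arrays = {f"param::{k}": t.data for k, t in params.tensors.items()}
    arrays["config_json"] = np.array(json.dumps(asdict(config)))
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    with np.load(path, allow_pickle=False) as z:
        cfg_raw = json.loads(str(z["config_json"]))
        cfg_raw["modalities"] = tuple(cfg_raw["modalities"])
        config = ModelConfig(**cfg_raw)
        tensors = {
            k.split("::", 1)[1]: Tensor(z[k], requires_grad=True)
            for k in z.files if k.startswith("param::")
        }
    return ModelParams(tensors), config
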