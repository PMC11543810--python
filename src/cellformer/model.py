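"""The graph-transformer network over cells.

Cells are nodes; their highly-variable-gene profiles are node features.
A shallow fully connected layer embeds each cell into a d-dimensional
latent space, after which K transformer layers exchange information
between *all* pairs of cells.  Softmax attention over all pairs costs
O(N²); here the exponential is replaced by its first-order Taylor
expansion, exp(q·k) ≈ 1 + q̂·k̂ with row-L2-normalised queries and keys,
which factorises the all-pair sum and brings the cost down to O(N·d²)
while keeping the weights nonnegative and row-stochastic:

    z_i ← ( Σ_j v_j + (Σ_j k̂_j v_jᵀ)ᵀ q̂_i ) / ( N + q̂_iᵀ Σ_l k̂_l )

When a kNN cell graph is supplied, a GCN term D^{-1/2} A D^{-1/2} V is
added to the attention output and blended with mixing weight β; the
graph is an optional structural bias, not a requirement.

All trainable tensors live in :class:`ModelParams`; forward passes are
pure functions of (input, params), so inference is plain NumPy and
training differentiates the same code through the autodiff tape.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .graph import CellGraph, normalize_adjacency
from .io_preprocess import ExpressionMatrix

__all__ = [
    "ModelConfig",
    "ModelParams",
    "LayerState",
    "AttentionMap",
    "FlopCounter",
    "flops",
    "init_params",
    "make_layer_state",
    "embed_cells",
    "softmax_attention_reference",
    "linear_attention",
    "gcn_propagate",
    "fuse_and_update",
    "classify",
    "forward",
    "materialize_attention",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_TAG = "cellformer-ckpt-v1"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    d : embedding width; must be divisible by n_heads.
    n_layers : number of transformer layers K (two by default).
    beta : mixing weight of the GCN branch in [0, 1]; ignored when
        use_graph is False.
    activation : nonlinearity σ′ after each layer's LayerNorm.
    epsilon : guard for normalisations and denominators.
    """

    d: int = 128
    n_layers: int = 2
    n_heads: int = 4
    beta: float = 0.5
    use_graph: bool = False
    activation: str = "relu"
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise ValueError(f"d={self.d} not divisible by n_heads={self.n_heads}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads


class ModelParams:
    """All trainable arrays, keyed by name; shapes fixed by (config, ĝ, C)."""

    def __init__(self, arrays: dict[str, np.ndarray], n_genes: int, n_classes: int):
        self.arrays = arrays
        self.n_genes = n_genes
        self.n_classes = n_classes
        for v in arrays.values():
            if not np.all(np.isfinite(v)):
                raise ValueError("non-finite parameter value")

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: v.copy() for k, v in self.arrays.items()}, self.n_genes, self.n_classes
        )

    def as_tensors(self, requires_grad: bool = True) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=requires_grad) for k, v in self.arrays.items()}


def init_params(config: ModelConfig, n_genes: int, n_classes: int) -> ModelParams:
    """Glorot-uniform initialisation, deterministic in config.seed."""
    rng = np.random.default_rng(config.seed)
    d, hd = config.d, config.head_dim

    def glorot(fan_out, fan_in):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_out, fan_in))

    arrays: dict[str, np.ndarray] = {
        "W1": glorot(d, n_genes),
        "b1": np.zeros(d),
        "ln0_g": np.ones(d),
        "ln0_b": np.zeros(d),
        "W_out": glorot(n_classes, d),
        "b_out": np.zeros(n_classes),
    }
    for k in range(config.n_layers):
        arrays[f"layer{k}.Wq"] = np.stack([glorot(hd, d) for _ in range(config.n_heads)])
        arrays[f"layer{k}.Wk"] = np.stack([glorot(hd, d) for _ in range(config.n_heads)])
        arrays[f"layer{k}.Wv"] = np.stack([glorot(hd, d) for _ in range(config.n_heads)])
        arrays[f"layer{k}.ln_g"] = np.ones(d)
        arrays[f"layer{k}.ln_b"] = np.zeros(d)
    return ModelParams(arrays, n_genes, n_classes)


# ---------------------------------------------------------------------------
# Instrumentation


class FlopCounter:
    """Counts multiply-add operations of the linear attention path."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0

    def add(self, n: int):
        self.count += int(n)


#: module-level counter; linear attention charges its multiply-adds here
flops = FlopCounter()


# ---------------------------------------------------------------------------
# Layer state


@dataclass
class LayerState:
    """Per-layer, per-head attention intermediates for a batch of n cells."""

    Z: np.ndarray                       # n × d embeddings entering the layer
    Q: list[np.ndarray]                 # per head, n × head_dim
    K: list[np.ndarray]
    V: list[np.ndarray]
    Q_hat: list[np.ndarray] = field(default_factory=list)  # unit rows
    K_hat: list[np.ndarray] = field(default_factory=list)


def _x_array(x) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        return x.dense()
    return np.asarray(x, dtype=np.float64)


def make_layer_state(z: np.ndarray, params: ModelParams, config: ModelConfig,
                     layer: int) -> LayerState:
    """Project embeddings to per-head Q, K, V and their unit-row forms."""
    eps = config.epsilon
    Q, K, V, Qh, Kh = [], [], [], [], []
    for h in range(config.n_heads):
        q = z @ params.arrays[f"layer{layer}.Wq"][h].T
        k = z @ params.arrays[f"layer{layer}.Wk"][h].T
        v = z @ params.arrays[f"layer{layer}.Wv"][h].T
        Q.append(q)
        K.append(k)
        V.append(v)
        Qh.append(q / np.sqrt((q**2).sum(axis=1, keepdims=True) + eps))
        Kh.append(k / np.sqrt((k**2).sum(axis=1, keepdims=True) + eps))
    return LayerState(Z=z, Q=Q, K=K, V=V, Q_hat=Qh, K_hat=Kh)


# ---------------------------------------------------------------------------
# Core operations (NumPy-facing; training reuses the tensor-level kernels)


def embed_cells(x_hat, params: ModelParams, config: ModelConfig) -> np.ndarray:
    """Initial embedding Z⁰ = ReLU(LayerNorm(W₁x + b₁)) for each cell."""
    x = _x_array(x_hat)
    if x.shape[1] != params.n_genes:
        raise ValueError(
            f"input has {x.shape[1]} genes but params expect {params.n_genes}"
        )
    pt = params.as_tensors(requires_grad=False)
    return _embed_t(Tensor(x), pt, config).data


def _embed_t(xt: Tensor, pt: dict[str, Tensor], config: ModelConfig) -> Tensor:
    h = ag.matmul(xt, pt["W1"].T) + pt["b1"]
    return ag.relu(ag.layer_norm(h, pt["ln0_g"], pt["ln0_b"], config.epsilon))


def softmax_attention_reference(state: LayerState) -> np.ndarray:
    """Exact softmax attention by explicit O(N²) double loops (test oracle).

    Never used on the main path; kept as the semantic reference the
    linearised attention approximates.
    """
    n = state.Z.shape[0]
    outs = []
    for q, k, v in zip(state.Q, state.K, state.V):
        out = np.zeros_like(v)
        for i in range(n):
            logits = np.array([q[i] @ k[j] for j in range(n)])
            logits -= logits.max()
            w = np.exp(logits)
            w /= w.sum()
            for j in range(n):
                out[i] += w[j] * v[j]
        outs.append(out)
    return np.concatenate(outs, axis=1)


def _linear_attention_head_t(qn: Tensor, kn: Tensor, v: Tensor, n: int,
                             eps: float, counter: FlopCounter) -> Tensor:
    """Factored Taylor attention for one head on unit-row q̂, k̂."""
    hd = v.shape[1]
    sv = v.sum(axis=0, keepdims=True)                 # Σ_j v_j
    m = ag.matmul(kn.T, v)                            # Σ_j k̂_j v_jᵀ
    num = sv + ag.matmul(qn, m)
    sk = kn.sum(axis=0, keepdims=True)                # Σ_l k̂_l
    den = float(n) + ag.matmul(qn, sk.T)              # n × 1
    if den.data.min() < eps:
        raise ValueError("degenerate attention normalizer")
    counter.add(2 * n * hd * hd + 4 * n * hd)         # K̂ᵀV, Q̂M, sums, q̂·Σk̂, divide
    return num / den


def linear_attention(state: LayerState, epsilon: float = 1e-8) -> np.ndarray:
    """All-pair attention via the factored first-order Taylor form, O(N·d²).

    Numerically equivalent (to ~1e-5 relative) to evaluating the
    normalised weights (1 + q̂_i·k̂_j) / (N + q̂_i·Σ_l k̂_l) against every
    pair explicitly; heads are concatenated.
    """
    n = state.Z.shape[0]
    outs = []
    for qn, kn, v in zip(state.Q_hat, state.K_hat, state.V):
        out = _linear_attention_head_t(Tensor(qn), Tensor(kn), Tensor(v),
                                       n, epsilon, flops)
        outs.append(out.data)
    return np.concatenate(outs, axis=1)


def gcn_propagate(z_attn: np.ndarray, v: np.ndarray, a_norm: np.ndarray) -> np.ndarray:
    """Graph branch: Z + D^{-1/2} A D^{-1/2} V."""
    if a_norm.shape[0] != z_attn.shape[0] or v.shape != z_attn.shape:
        raise ValueError("shape mismatch between embeddings, values and adjacency")
    return z_attn + a_norm @ v


def fuse_and_update(branch_out: np.ndarray, z_prev: np.ndarray, beta: float,
                    config: ModelConfig, params: ModelParams, layer: int) -> np.ndarray:
    """Residual update Z⁽ᵏ⁺¹⁾ = σ′(LayerNorm(β·branch + (1−β)·Z⁽ᵏ⁾)).

    ``branch_out`` is the layer's aggregation output — the attention
    result alone, or the GCN-fused form Z_attn + D^{-1/2}AD^{-1/2}V when
    a graph is supplied — and ``z_prev`` is the embedding entering the
    layer.  Keeping the layer input in the blend is what lets per-cell
    identity survive the near-uniform all-pair averaging: without it the
    across-cell variance of the activations contracts by roughly 1/√N
    per layer and the stack collapses to a constant map.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    pt = params.as_tensors(requires_grad=False)
    mixed = beta * Tensor(branch_out) + (1.0 - beta) * Tensor(z_prev)
    out = ag.layer_norm(mixed, pt[f"layer{layer}.ln_g"], pt[f"layer{layer}.ln_b"],
                        config.epsilon)
    if config.activation == "relu":
        out = ag.relu(out)
    return out.data


def classify(zK: np.ndarray, params: ModelParams) -> np.ndarray:
    """Output head: logits Ŷ = Z⁽ᴷ⁾Wᵀ + b (no softmax; the loss applies it)."""
    return np.asarray(zK) @ params.arrays["W_out"].T + params.arrays["b_out"]


# ---------------------------------------------------------------------------
# Full forward (tensor-level; shared by inference and training)


def _layer_t(zt: Tensor, pt: dict[str, Tensor], config: ModelConfig, layer: int,
             a_norm: Optional[np.ndarray], counter: FlopCounter,
             capture: Optional[list] = None) -> Tensor:
    n = zt.shape[0]
    eps = config.epsilon
    attn_heads, v_heads = [], []
    cap_q, cap_k = [], []
    for h in range(config.n_heads):
        wq = pt[f"layer{layer}.Wq"]
        wk = pt[f"layer{layer}.Wk"]
        wv = pt[f"layer{layer}.Wv"]
        q = ag.matmul(zt, _head(wq, h).T)
        k = ag.matmul(zt, _head(wk, h).T)
        v = ag.matmul(zt, _head(wv, h).T)
        qn = ag.l2_normalize_rows(q, eps)
        kn = ag.l2_normalize_rows(k, eps)
        if capture is not None:
            cap_q.append(qn.data.copy())
            cap_k.append(kn.data.copy())
        attn_heads.append(_linear_attention_head_t(qn, kn, v, n, eps, counter))
        v_heads.append(v)
    z_attn = ag.concat_cols(attn_heads)
    if capture is not None:
        capture.append({"Q_hat": cap_q, "K_hat": cap_k})
    use_graph = config.use_graph and a_norm is not None
    if use_graph:
        v_full = ag.concat_cols(v_heads)
        branch = z_attn + ag.matmul(Tensor(a_norm), v_full)
    else:
        branch = z_attn
    # residual blend with the layer input (see fuse_and_update)
    mixed = config.beta * branch + (1.0 - config.beta) * zt
    out = ag.layer_norm(mixed, pt[f"layer{layer}.ln_g"], pt[f"layer{layer}.ln_b"], eps)
    if config.activation == "relu":
        out = ag.relu(out)
    return out


def _head(w: Tensor, h: int) -> Tensor:
    """Slice one head out of a stacked (heads, hd, d) parameter tensor."""
    out = ag.astensor(w.data[h])
    out._parents = (w,)

    def bwd():
        if w.grad is None:
            w.grad = np.zeros_like(w.data)
        w.grad[h] += out.grad

    out._backward = bwd
    return out


def _forward_t(xt: Tensor, pt: dict[str, Tensor], config: ModelConfig,
               a_norm: Optional[np.ndarray], counter: FlopCounter,
               capture: Optional[list] = None) -> Tensor:
    zt = _embed_t(xt, pt, config)
    for k in range(config.n_layers):
        zt = _layer_t(zt, pt, config, k, a_norm, counter, capture)
    return ag.matmul(zt, pt["W_out"].T) + pt["b_out"]


def forward(x_hat, graph: Optional[CellGraph], config: ModelConfig,
            params: ModelParams, add_self_loops: bool = False) -> np.ndarray:
    """Full network: embed → K × (attention [+ GCN] → fuse) → logits.

    Permutation-equivariant in the cell order (no positional encoding);
    with ``use_graph=False`` any supplied graph is ignored.
    """
    x = _x_array(x_hat)
    if x.shape[1] != params.n_genes:
        raise ValueError(
            f"input has {x.shape[1]} genes but params expect {params.n_genes}"
        )
    a_norm = None
    if config.use_graph and graph is not None:
        if graph.n_cells != x.shape[0]:
            raise ValueError("graph must cover exactly the input cells")
        a_norm = normalize_adjacency(graph, add_self_loops=add_self_loops)
    pt = params.as_tensors(requires_grad=False)
    return _forward_t(Tensor(x), pt, config, a_norm, flops).data


# ---------------------------------------------------------------------------
# Attention materialisation


@dataclass(frozen=True)
class AttentionMap:
    """Explicit row-stochastic cell × cell attention weights at one layer."""

    layer: int
    matrix: np.ndarray

    def __post_init__(self):
        if (self.matrix < 0).any():
            raise ValueError("attention weights must be nonnegative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1")


def materialize_attention(x_hat, graph: Optional[CellGraph], config: ModelConfig,
                          params: ModelParams, layer: int, max_n: int = 20000,
                          head: Optional[int] = None) -> AttentionMap:
    """Materialise the n×n Taylor-attention weights at one layer.

    weights[i, j] = (1 + q̂_i·k̂_j) / (N + q̂_i·Σ_l k̂_l), computed from the
    same forward states the network itself uses.  With ``head=None`` the
    per-head matrices are averaged (each is row-stochastic, so the mean
    is too); pass a head index for a single head's map.
    """
    x = _x_array(x_hat)
    n = x.shape[0]
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds max_n={max_n}; subsample cells before materialising"
        )
    if not 0 <= layer < config.n_layers:
        raise ValueError(f"layer {layer} out of range [0, {config.n_layers})")
    a_norm = None
    if config.use_graph and graph is not None:
        a_norm = normalize_adjacency(graph)
    pt = params.as_tensors(requires_grad=False)
    capture: list = []
    _forward_t(Tensor(x), pt, config, a_norm, flops, capture)
    qs, ks = capture[layer]["Q_hat"], capture[layer]["K_hat"]
    heads = range(config.n_heads) if head is None else [head]
    mats = []
    for h in heads:
        qn, kn = qs[h], ks[h]
        w = 1.0 + qn @ kn.T                       # nonneg: unit rows ⇒ q̂·k̂ ≥ −1
        w = w / (n + qn @ kn.sum(axis=0))[:, None]
        mats.append(w)
    return AttentionMap(layer=layer, matrix=np.mean(mats, axis=0))


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(path, params: ModelParams, config: ModelConfig,
                    vocabulary: Sequence[str],
                    kept_gene_indices: Optional[np.ndarray] = None,
                    gene_names: Optional[Sequence[str]] = None) -> None:
    """Single-archive checkpoint: config JSON + parameter tensors + label
    vocabulary + kept gene indices (and optionally the kept gene names,
    letting a query be aligned by name), tagged with a format version."""
    meta = {
        "format": CHECKPOINT_TAG,
        "config": asdict(config),
        "vocabulary": list(vocabulary),
        "n_genes": params.n_genes,
        "n_classes": params.n_classes,
        "gene_names": None if gene_names is None else list(gene_names),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = io.BytesIO()
        arrays = dict(params.arrays)
        if kept_gene_indices is not None:
            arrays["__kept_gene_indices__"] = np.asarray(kept_gene_indices)
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig, list[str], Optional[np.ndarray]]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format") != CHECKPOINT_TAG:
            raise ValueError(f"unrecognised checkpoint format {meta.get('format')!r}")
        with zf.open("arrays.npz") as fh:
            npz = np.load(io.BytesIO(fh.read()))
            arrays = {k: npz[k] for k in npz.files}
    kept = arrays.pop("__kept_gene_indices__", None)
    config = ModelConfig(**meta["config"])
    params = ModelParams(arrays, meta["n_genes"], meta["n_classes"])
    params.gene_names = meta.get("gene_names")  # type: ignore[attr-defined]
    return params, config, list(meta["vocabulary"]), kept
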