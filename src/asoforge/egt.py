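"""Edge-augmented graph transformer (EGT) ranker.

The model maintains two channels through every layer: node embeddings
``H`` (one vector per atom) and edge embeddings ``E`` (one vector per
ordered atom pair, initialised from bond features). Each layer runs
multi-head attention over nodes in which the attention logits are
*additively biased* and *multiplicatively gated* by learned transforms
of the edge channel, and the edge channel itself is updated from the
pre-softmax attention logits. A masked mean over node embeddings feeds
a small head that emits one scalar per graph: the predicted relative
efficacy score f(x). Scores are only meaningful as an ordering — the
model is trained with a pairwise hinge objective, not to regress
absolute inhibition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, einsum, layer_norm
from .errors import CheckpointError, ShapeMismatch
from .featurize import EDGE_DIM, NODE_DIM, GraphFeatures, pad_batch

_NEG = 1e9  # additive mask for padded attention targets


@dataclass(frozen=True)
class EGTConfig:
    """Architecture and training hyperparameters of the ranker.

    ``node_dim`` must be divisible by ``num_heads``. The margin ``t`` is
    the pairwise hinge margin; see :func:`pairwise_hinge_loss`.
    """

    num_layers: int = 2
    num_heads: int = 4
    node_dim: int = 32
    edge_dim: int = 8
    ffn_mult: int = 2
    dropout: float = 0.0
    margin: float = 0.1
    pooling: str = "sum"
    learning_rate: float = 1e-3
    batch_pairs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_dim % self.num_heads != 0:
            raise ValueError("node_dim must be divisible by num_heads")
        if self.margin < 0:
            raise ValueError("margin t must be nonnegative")
        if self.pooling not in ("mean", "sum"):
            raise ValueError("pooling must be 'mean' or 'sum'")


def _init_params(config: EGTConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    d, de, h = config.node_dim, config.edge_dim, config.num_heads
    f = config.ffn_mult

    def mat(name, n_in, n_out, params):
        scale = np.sqrt(2.0 / (n_in + n_out))
        params[name] = Tensor(
            rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32),
            requires_grad=True,
        )
        params[name + "_b"] = Tensor(
            np.zeros(n_out, dtype=np.float32), requires_grad=True
        )

    def norm(name, dim, params):
        params[name + "_g"] = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        params[name + "_b"] = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    p: dict[str, Tensor] = {}
    mat("embed_n", NODE_DIM, d, p)
    mat("embed_e", EDGE_DIM, de, p)
    for i in range(config.num_layers):
        pre = f"layer{i}."
        norm(pre + "ln_h", d, p)
        norm(pre + "ln_e", de, p)
        mat(pre + "wq", d, d, p)
        mat(pre + "wk", d, d, p)
        mat(pre + "wv", d, d, p)
        mat(pre + "edge_bias", de, h, p)
        mat(pre + "edge_gate", de, h, p)
        mat(pre + "wo", d, d, p)
        mat(pre + "edge_out", h, de, p)
        norm(pre + "ln_h2", d, p)
        mat(pre + "ffn1", d, f * d, p)
        mat(pre + "ffn2", f * d, d, p)
    norm("ln_final", d, p)
    mat("head1", d, d, p)
    mat("head2", d, 1, p)
    return p


@dataclass
class RankerModel:
    """A (possibly trained) EGT ranker: parameter collection + config."""

    params: dict[str, Tensor]
    config: EGTConfig
    loss_history: list[float] = field(default_factory=list)

    @classmethod
    def initialize(cls, config: EGTConfig) -> "RankerModel":
        rng = np.random.default_rng(config.seed)
        return cls(params=_init_params(config, rng), config=config)

    @property
    def version_id(self) -> str:
        """Content hash of the parameters and config; changes iff they do."""
        digest = hashlib.sha256()
        digest.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(self.params[name].data.astype(np.float32).tobytes())
        return digest.hexdigest()[:16]

    # -- forward pass ------------------------------------------------------

    def forward(
        self,
        nodes: np.ndarray,
        edges: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Score a padded batch: (B, N, 15), (B, N, N, 7), (B, N) -> (B,)."""
        if nodes.shape[-1] != NODE_DIM or edges.shape[-1] != EDGE_DIM:
            raise ShapeMismatch(
                f"expected node dim {NODE_DIM} and edge dim {EDGE_DIM}, got"
                f" {nodes.shape[-1]} and {edges.shape[-1]}"
            )
        p = self.params
        cfg = self.config
        h, d = cfg.num_heads, cfg.node_dim
        dk = d // h
        b, n = mask.shape

        def lin(x: Tensor, name: str) -> Tensor:
            lead = "uvwx"[: x.data.ndim - 1]
            return einsum(f"{lead}i,ij->{lead}j", x, p[name]) + p[name + "_b"]

        def dropout(x: Tensor) -> Tensor:
            if not training or cfg.dropout <= 0.0:
                return x
            if rng is None:
                raise ValueError("dropout requires an RNG in training mode")
            keep = (rng.random(x.shape) >= cfg.dropout).astype(np.float32)
            return x * Tensor(keep / (1.0 - cfg.dropout))

        H = lin(Tensor(nodes), "embed_n")
        E = lin(Tensor(edges), "embed_e")
        att_mask = Tensor(((mask[:, None, :, None] - 1.0) * _NEG).astype(np.float32))

        for i in range(cfg.num_layers):
            pre = f"layer{i}."
            Hn = layer_norm(H, p[pre + "ln_h_g"], p[pre + "ln_h_b"])
            En = layer_norm(E, p[pre + "ln_e_g"], p[pre + "ln_e_b"])
            Q = lin(Hn, pre + "wq").reshape(b, n, h, dk)
            K = lin(Hn, pre + "wk").reshape(b, n, h, dk)
            V = lin(Hn, pre + "wv").reshape(b, n, h, dk)
            logits = einsum("bihk,bjhk->bijh", Q, K) * (1.0 / np.sqrt(dk))
            logits = logits + lin(En, pre + "edge_bias")
            gate = lin(En, pre + "edge_gate").sigmoid()
            att = (logits + att_mask).softmax(axis=2) * gate
            agg = einsum("bijh,bjhk->bihk", att, V).reshape(b, n, d)
            H = H + dropout(lin(agg, pre + "wo"))
            Hn2 = layer_norm(H, p[pre + "ln_h2_g"], p[pre + "ln_h2_b"])
            H = H + dropout(lin(lin(Hn2, pre + "ffn1").relu(), pre + "ffn2"))
            E = E + lin(logits, pre + "edge_out")

        Hf = layer_norm(H, p["ln_final_g"], p["ln_final_b"])
        m = Tensor(mask[:, :, None])
        pooled = (Hf * m).sum(axis=1)
        if cfg.pooling == "mean":
            pooled = pooled * Tensor(
                (1.0 / np.maximum(mask.sum(axis=1), 1.0))[:, None].astype(np.float32)
            )
        out = lin(lin(pooled, "head1").relu(), "head2")
        return out.reshape(b)


def score(model: RankerModel, feats: GraphFeatures) -> float:
    """Score a single featurized graph in inference mode (deterministic)."""
    return float(score_batch(model, [feats])[0])


def score_batch(model: RankerModel, feats: list[GraphFeatures]) -> np.ndarray:
    """Score a list of featurized graphs; returns an (n,) float array."""
    nodes, edges, mask = pad_batch(feats)
    with ad.inference_mode():
        out = model.forward(nodes, edges, mask, training=False)
    values = np.asarray(out.data, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite score")
    return values


def pairwise_hinge_loss(s_pos: float, s_neg: float, t: float) -> float:
    """Margin ranking loss ``max(0, t + s_neg - s_pos)``.

    Zero iff the better sample out-scores the worse one by at least the
    margin ``t``; a tie costs exactly ``t``.
    """
    if t < 0:
        raise ValueError("margin t must be nonnegative")
    return max(0.0, t + s_neg - s_pos)


def hinge_loss_tensor(s_pos: Tensor, s_neg: Tensor, t: float) -> Tensor:
    """Differentiable elementwise hinge over batched score tensors."""
    return (s_neg - s_pos + t).relu()


class RMSProp:
    """RMSProp: scale each step by a running RMS of recent gradients."""

    def __init__(
        self,
        params: dict[str, Tensor],
        learning_rate: float = 1e-3,
        decay: float = 0.9,
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.learning_rate = learning_rate
        self.decay = decay
        self.eps = eps
        self.clip_norm = clip_norm
        self._cache = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(
                    float((p.grad.astype(np.float64) ** 2).sum())
                    for p in self.params.values()
                    if p.grad is not None
                )
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for name, param in self.params.items():
            if param.grad is None:
                continue
            g = param.grad.astype(param.data.dtype) * param.data.dtype.type(scale)
            c = self._cache[name]
            c *= self.decay
            c += (1.0 - self.decay) * g * g
            param.data = param.data - self.learning_rate * g / (np.sqrt(c) + self.eps)

    def zero_grad(self) -> None:
        for param in self.params.values():
            param.grad = None


def save_checkpoint(path, model: RankerModel) -> None:
    """Write a self-describing checkpoint (config + parameters + hash)."""
    arrays = {f"param:{k}": v.data for k, v in model.params.items()}
    meta = json.dumps(
        {"config": asdict(model.config), "version_id": model.version_id}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> RankerModel:
    """Load a checkpoint, validating parameters against the stored config.

    Raises
    ------
    CheckpointError
        If parameter names/shapes disagree with the stored config or the
        content hash does not match.
    """
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        params = {
            k[len("param:"):]: Tensor(npz[k].copy(), requires_grad=True)
            for k in npz.files
            if k.startswith("param:")
        }
    config = EGTConfig(**meta["config"])
    reference = _init_params(config, np.random.default_rng(0))
    if set(reference) != set(params):
        raise CheckpointError("checkpoint parameter names do not match config")
    for name, ref in reference.items():
        if ref.data.shape != params[name].data.shape:
            raise CheckpointError(
                f"parameter {name} has shape {params[name].data.shape},"
                f" config implies {ref.data.shape}"
            )
    model = RankerModel(params=params, config=config)
    if model.version_id != meta["version_id"]:
        raise CheckpointError("checkpoint content hash mismatch")
    return model
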