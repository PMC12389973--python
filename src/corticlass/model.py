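"""Trainable architecture: attention feature enhancer, GCN, heads.

The forward path for one epoch sample is

    X [N x D] -> 4x multi-head self-attention layers (residual + ReLU)
              -> 2x graph convolution ReLU(A_hat H W)
              -> mean-pool over the N nodes -> linear class logits [2]

with a separate domain discriminator consuming the pooled features through a
gradient-reversal layer. The per-sample adjacency comes from thresholding
Pearson correlations of the broadband ROI series at phi (default 0.3), with
the diagonal forced to zero before the A + I renormalization

    A_hat = D^{-1/2} (A + I) D^{-1/2},  D = degree matrix of A + I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

DEFAULT_PHI = 0.3


# ---------------------------------------------------------------------------
# graph construction


@dataclass
class GraphSpec:
    adjacency: np.ndarray  # binary symmetric, zero diagonal
    a_hat: np.ndarray  # symmetric normalized, spectral radius <= 1
    threshold: float


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """A_hat = D^{-1/2} (A + I) D^{-1/2} with D the degree matrix of A + I."""
    a_tilde = np.asarray(adjacency, dtype=float) + np.eye(adjacency.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def build_adjacency(roi_series: np.ndarray, phi: float = DEFAULT_PHI) -> GraphSpec:
    """Pearson-threshold adjacency of ROI time series plus its normalization."""
    roi_series = np.asarray(roi_series, dtype=float)
    if roi_series.shape[0] < 2:
        raise ValueError("need at least 2 ROI series")
    if np.any(roi_series.std(axis=1) == 0):
        raise ValueError("constant ROI series: correlation undefined")
    corr = np.corrcoef(roi_series)
    adj = (corr >= phi).astype(np.int64)
    np.fill_diagonal(adj, 0)
    return GraphSpec(adjacency=adj, a_hat=normalize_adjacency(adj), threshold=phi)


# ---------------------------------------------------------------------------
# parameters / layers


def _param(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    scale = np.sqrt(2.0 / sum(shape))
    return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.w = _param(rng, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out

    def parameters(self) -> list[Tensor]:
        return [self.w] + ([self.b] if self.b is not None else [])


def attention_head(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor) -> Tensor:
    """Scaled dot-product self-attention: softmax(Q K^T / sqrt(d_k)) V."""
    q = x @ w_q
    k = x @ w_k
    v = x @ w_v
    d_k = w_k.shape[1]
    scores = (q @ k.T) * (1.0 / np.sqrt(d_k))
    return scores.softmax(axis=-1) @ v


def attention_weights(x: np.ndarray, w_q: np.ndarray, w_k: np.ndarray) -> np.ndarray:
    """The [N x N] softmax attention matrix (diagnostic; rows sum to 1)."""
    q, k = x @ w_q, x @ w_k
    s = q @ k.T / np.sqrt(w_k.shape[1])
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class FALayer:
    """One multi-head self-attention layer with residual add and ReLU.

    Per-head dimension is D // H when divisible, else D, with the output
    projection W_O mapping the concatenation back to D so the shape [N x D]
    is preserved.
    """

    def __init__(self, rng: np.random.Generator, d: int, heads: int):
        self.heads = heads
        d_h = d // heads if d % heads == 0 else d
        self.d_h = d_h
        self.w_q = [_param(rng, (d, d_h)) for _ in range(heads)]
        self.w_k = [_param(rng, (d, d_h)) for _ in range(heads)]
        self.w_v = [_param(rng, (d, d_h)) for _ in range(heads)]
        self.w_o = _param(rng, (heads * d_h, d))

    def __call__(self, x: Tensor) -> Tensor:
        outs = [attention_head(x, self.w_q[h], self.w_k[h], self.w_v[h])
                for h in range(self.heads)]
        return (x + Tensor.concat(outs, axis=1) @ self.w_o).relu()

    def parameters(self) -> list[Tensor]:
        return [*self.w_q, *self.w_k, *self.w_v, self.w_o]


class FAStack:
    """Four sequential FA layers (feature enhancement network)."""

    def __init__(self, rng: np.random.Generator, d: int, heads: int = 4,
                 n_layers: int = 4):
        self.layers = [FALayer(rng, d, heads) for _ in range(n_layers)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


def gcn_layer(h: Tensor, a_hat: Tensor, w: Tensor) -> Tensor:
    """H^{l+1} = ReLU(A_hat H^l W^l)."""
    return (a_hat @ h @ w).relu()


@dataclass(frozen=True)
class ModelConfig:
    d_in: int = 32
    heads: int = 4
    fa_layers: int = 4
    gcn_layers: int = 2
    hidden_dim: int = 512
    dropout: float = 0.3
    phi: float = DEFAULT_PHI
    discriminator_hidden: int = 256
    use_fa: bool = True


class DepressionClassifier:
    """Attention-enhanced GCN with classifier and domain-discriminator heads."""

    def __init__(self, config: ModelConfig, n_domains: int, seed: int = 0):
        self.config = config
        self.n_domains = n_domains
        rng = np.random.default_rng(seed)
        self.fa = FAStack(rng, config.d_in, config.heads, config.fa_layers) \
            if config.use_fa else None
        dims = [config.d_in] + [config.hidden_dim] * config.gcn_layers
        self.gcn_weights = [_param(rng, (dims[i], dims[i + 1]))
                            for i in range(config.gcn_layers)]
        self.classifier = Linear(rng, config.hidden_dim, 2)
        self.disc1 = Linear(rng, config.hidden_dim, config.discriminator_hidden)
        self.disc2 = Linear(rng, config.discriminator_hidden, n_domains)

    # -- forward -----------------------------------------------------------

    def extract(self, x: np.ndarray | Tensor, a_hat: np.ndarray | Tensor,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Pooled feature vector [1 x hidden] for one epoch sample."""
        h = x if isinstance(x, Tensor) else Tensor(x)
        a = a_hat if isinstance(a_hat, Tensor) else Tensor(a_hat)
        if self.fa is not None:
            h = self.fa(h)
        for w in self.gcn_weights:
            h = gcn_layer(h, a, w)
            if training and self.config.dropout > 0 and rng is not None:
                h = h.dropout(self.config.dropout, rng, training=True)
        return h.mean(axis=0, keepdims=True)

    def classify(self, pooled: Tensor) -> Tensor:
        return self.classifier(pooled)

    def discriminate(self, pooled: Tensor, lam: float) -> Tensor:
        """Domain logits through the gradient-reversal layer."""
        return self.disc2(self.disc1(pooled.grad_reverse(lam)).relu())

    # -- parameter plumbing --------------------------------------------------

    def extractor_parameters(self) -> list[Tensor]:
        params = list(self.gcn_weights)
        if self.fa is not None:
            params = self.fa.parameters() + params
        return params

    def discriminator_parameters(self) -> list[Tensor]:
        return self.disc1.parameters() + self.disc2.parameters()

    def parameters(self) -> list[Tensor]:
        return (self.extractor_parameters() + self.classifier.parameters()
                + self.discriminator_parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"p{i}"].copy()
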