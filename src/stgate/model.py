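"""The STGATE network and its ablation variants.

Architecture (full ``stgate`` variant):

1. **Transformer learning block (TLB)** — per-electrode 2-D convolutions over
   the (band, time) plane (3x3, 3x3, then 1x1, unpadded, so five bands
   collapse to one and the temporal axis shrinks by 4), followed by a
   pre-norm transformer encoder with a learned positional embedding over the
   reduced temporal sequence.  Output ``X_h`` has shape (B, N, C, T_r).
2. **Spatial attention** — ``S = V_s tanh(W1 X_h W2 + b_s)`` produces a
   per-sample N x N score matrix which is standardized over the mini-batch
   and Top-K sparsified per row into the dynamic adjacency ``A``.
3. **Temporal attention** — the mirrored construction on the transposed
   tensor yields a T_r x T_r map used to reweight ``X_h`` along time.
4. **Graph attention (GAT)** — multi-head attention over each node's
   neighborhood (the nonzero entries of its adjacency row plus a mandatory
   self-loop); retained adjacency weights are added to the attention logits
   so the dynamic adjacency is trained end-to-end.  Head outputs are
   averaged and passed through an ELU.
5. **Readout** — mean over nodes, dropout, linear map to class logits.

Ablation variants re-wire these blocks: ``baseline`` (convolutions only),
``tlb``, ``sgat``, ``tgat`` (temporal attention with a static kNN graph),
``sgat_tlb``, ``tgat_tlb``, ``stgat`` and the full ``stgate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Parameter, Tensor, softmax
from .errors import ConfigurationError, DataError
from .graph import DEFAULT_KNN_K, DEFAULT_TOP_K, topk_mask

VARIANTS = ("baseline", "tlb", "sgat", "tgat", "sgat_tlb", "tgat_tlb", "stgat", "stgate")

_WITH_TRANSFORMER = frozenset({"tlb", "sgat_tlb", "tgat_tlb", "stgate"})
_WITH_SPATIAL = frozenset({"sgat", "sgat_tlb", "stgat", "stgate"})
_WITH_TEMPORAL = frozenset({"tgat", "tgat_tlb", "stgat", "stgate"})

CONV_TIME_SHRINK = 4  # two unpadded 3x3 convolutions: T -> T - 4, bands 5 -> 1


@dataclass
class TLBParams:
    conv_channels: int = 32
    depth: int = 2
    heads: int = 4
    ff_width: int | None = None  # default 2 * conv_channels

    def __post_init__(self):
        if self.ff_width is None:
            self.ff_width = 2 * self.conv_channels
        if self.conv_channels % self.heads != 0:
            raise ConfigurationError(
                f"conv channel width {self.conv_channels} not divisible by "
                f"{self.heads} transformer heads"
            )


@dataclass
class GATParams:
    heads: int = 4
    out_features: int = 32

    def __post_init__(self):
        if self.heads < 1:
            raise ConfigurationError("GAT needs at least one head")


@dataclass
class ModelConfig:
    variant: str = "stgate"
    n_classes: int = 3
    k_top: int = DEFAULT_TOP_K
    k_nn: int = DEFAULT_KNN_K
    dropout: float = 0.3
    seq_len: int = 10  # consecutive feature windows per sample (T)
    tlb: TLBParams = field(default_factory=TLBParams)
    gat: GATParams = field(default_factory=GATParams)
    knn_warm_start: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.seq_len <= CONV_TIME_SHRINK:
            raise ConfigurationError(
                f"seq_len must exceed {CONV_TIME_SHRINK} (got {self.seq_len})"
            )

    @property
    def uses_transformer(self) -> bool:
        return self.variant in _WITH_TRANSFORMER

    @property
    def uses_spatial(self) -> bool:
        return self.variant in _WITH_SPATIAL

    @property
    def uses_temporal(self) -> bool:
        return self.variant in _WITH_TEMPORAL

    @property
    def uses_gat(self) -> bool:
        return self.uses_spatial or self.uses_temporal


class ConvStack(nn.Module):
    """Per-electrode multi-kernel convolution stack over the (band, time) plane.

    Electrodes share weights and are treated as batch entries.  Kernels:
    3x3 -> 3x3 -> 1x1, all unpadded, so a 5-band axis collapses to 1 and the
    temporal axis shrinks by 4.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv1 = nn.Conv2d(1, channels, (3, 3), rng)
        self.conv2 = nn.Conv2d(channels, channels, (3, 3), rng)
        self.conv3 = nn.Conv2d(channels, channels, (1, 1), rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, f, t = x.shape
        if f != 5:
            raise ConfigurationError(
                f"band axis must have 5 entries for the 3x3/3x3 stack, got {f}"
            )
        if t <= CONV_TIME_SHRINK:
            raise ConfigurationError(
                f"temporal axis must exceed {CONV_TIME_SHRINK}, got {t}"
            )
        h = x.reshape(b * n, 1, f, t)
        h = self.conv1(h).elu()
        h = self.conv2(h).elu()
        h = self.conv3(h)  # (B*N, C, 1, T-4)
        return h.reshape(b, n, self.channels, t - CONV_TIME_SHRINK)


class SpatialAttention(nn.Module):
    """Dynamic adjacency: S = V_s tanh(W1 X_h W2 + b_s), standardized, Top-K."""

    def __init__(self, n_nodes: int, channels: int, t_r: int, k_top: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_nodes = n_nodes
        self.k_top = k_top
        self.v = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_nodes), (n_nodes, n_nodes)))
        self.w1 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(t_r), t_r))
        self.w2 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(channels), (channels, n_nodes)))
        self.b = Parameter(np.zeros((n_nodes, n_nodes)))
        self.norm = nn.ScalarBatchNorm()

    def forward(self, xh: Tensor):
        """Return ``(A_std, A_topk, keep_mask)`` for X_h of shape (B,N,C,T_r)."""
        b, n, c, t_r = xh.shape
        if n != self.n_nodes:
            raise ConfigurationError(
                f"spatial attention built for N={self.n_nodes}, input has N={n}"
            )
        m = (xh @ self.w1.reshape(t_r, 1)).reshape(b, n, c)  # contract T_r with W1
        scores = self.v @ (m @ self.w2 + self.b).tanh()  # (B, N, N)
        a_std = self.norm(scores)
        keep = topk_mask(a_std.data, self.k_top)
        return a_std, a_std * Tensor(keep.astype(float)), keep


class TemporalAttention(nn.Module):
    """Temporal map: the spatial construction mirrored on the transposed tensor."""

    def __init__(self, n_nodes: int, channels: int, t_r: int, rng: np.random.Generator):
        super().__init__()
        self.t_r = t_r
        self.v = Parameter(rng.normal(0.0, 1.0 / np.sqrt(t_r), (t_r, t_r)))
        self.u3 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_nodes), n_nodes))
        self.u4 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(channels), (channels, t_r)))
        self.b = Parameter(np.zeros((t_r, t_r)))
        self.norm = nn.ScalarBatchNorm()

    def forward(self, xh: Tensor) -> Tensor:
        b, n, c, t_r = xh.shape
        if t_r != self.t_r:
            raise ConfigurationError(
                f"temporal attention built for T_r={self.t_r}, input has T_r={t_r}"
            )
        xt = xh.transpose(0, 3, 2, 1)  # (B, T_r, C, N)
        m = (xt @ self.u3.reshape(n, 1)).reshape(b, t_r, c)  # contract N with U3
        scores = self.v @ (m @ self.u4 + self.b).tanh()  # (B, T_r, T_r)
        return self.norm(scores)


def apply_temporal(t_hat: Tensor, xh: Tensor) -> Tensor:
    """Reweight X_h along time: X̂[b,n,c,:] = T̂[b] · X_h[b,n,c,:]."""
    b, n, c, t_r = xh.shape
    if t_hat.shape != (b, t_r, t_r):
        raise ConfigurationError(
            f"temporal map shape {t_hat.shape} does not match X_h {xh.shape}"
        )
    xr = xh.transpose(0, 3, 1, 2).reshape(b, t_r, n * c)
    out = t_hat @ xr  # (B, T_r, N*C)
    return out.reshape(b, t_r, n, c).transpose(0, 2, 3, 1)


class GATLayer(nn.Module):
    """Multi-head graph attention over masked neighborhoods.

    Neighborhood of node i = nonzero entries of row i of the adjacency plus a
    mandatory self-loop.  Per head, logits are
    ``LeakyReLU(a_src·Wh_i + a_dst·Wh_j) [+ A_ij]`` with softmax over the
    neighborhood; the optional additive ``A_ij`` term carries gradient back
    into the learned adjacency.  Head outputs are averaged, then ELU.
    """

    LEAKY_SLOPE = 0.2

    def __init__(self, in_features: int, out_features: int, heads: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.heads = heads
        k, f_in, f_out = heads, in_features, out_features
        self.w = Parameter(nn.glorot(rng, (k, f_in, f_out), f_in, f_out))
        self.a_src = Parameter(nn.glorot(rng, (k, f_out), f_out, 1))
        self.a_dst = Parameter(nn.glorot(rng, (k, f_out), f_out, 1))
        self.drop = nn.Dropout(dropout)
        self._last_alpha: np.ndarray | None = None

    def forward(self, h: Tensor, neighborhood: np.ndarray,
                adjacency: Tensor | None = None) -> Tensor:
        b, n, f_in = h.shape
        if not np.all(np.isfinite(neighborhood if adjacency is None else adjacency.data)):
            raise DataError("non-finite adjacency passed to GAT layer")
        k = self.heads
        wh = h.reshape(b, 1, n, f_in) @ self.w  # (B, K, N, F')
        s_src = (wh * self.a_src.reshape(1, k, 1, -1)).sum(axis=-1)  # (B, K, N)
        s_dst = (wh * self.a_dst.reshape(1, k, 1, -1)).sum(axis=-1)
        logits = (s_src.reshape(b, k, n, 1) + s_dst.reshape(b, k, 1, n)).leaky_relu(
            self.LEAKY_SLOPE
        )
        if adjacency is not None:
            logits = logits + adjacency.reshape(b, 1, n, n)
        mask = np.asarray(neighborhood, dtype=bool) | np.eye(n, dtype=bool)
        if mask.ndim == 2:
            mask = mask[None, :, :]
        logits = logits + Tensor(np.where(mask[:, None, :, :], 0.0, -1e9))
        alpha = softmax(logits, axis=-1)
        self._last_alpha = alpha.data
        alpha = self.drop(alpha)
        out = (alpha @ wh).mean(axis=1)  # average heads: (B, N, F')
        return out.elu()


class STGATE(nn.Module):
    """Spatial-temporal graph attention network with a transformer encoder.

    ``static_adjacency`` (a binary N x N matrix, typically from
    :func:`stgate.graph.knn_graph`) is required for the ``tgat``/``tgat_tlb``
    variants, which have no spatial attention to build a dynamic graph.
    """

    def __init__(self, cfg: ModelConfig, n_channels: int,
                 static_adjacency: np.ndarray | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.n_channels = n_channels
        c = cfg.tlb.conv_channels
        t_r = cfg.seq_len - CONV_TIME_SHRINK
        self.t_r = t_r
        self.conv = ConvStack(c, rng)
        if cfg.uses_transformer:
            self.transformer = nn.TransformerEncoder(
                t_r, c, cfg.tlb.depth, cfg.tlb.heads, cfg.tlb.ff_width,
                cfg.dropout, rng,
            )
        if cfg.uses_spatial:
            self.spatial = SpatialAttention(n_channels, c, t_r, cfg.k_top, rng)
            if cfg.knn_warm_start and static_adjacency is not None:
                self.spatial.b.data += np.asarray(static_adjacency, dtype=float)
        if cfg.uses_temporal:
            self.temporal = TemporalAttention(n_channels, c, t_r, rng)
        readout_in = c * t_r
        if cfg.uses_gat:
            self.gat = GATLayer(c * t_r, cfg.gat.out_features, cfg.gat.heads,
                                cfg.dropout, rng)
            readout_in = cfg.gat.out_features
        needs_static = cfg.uses_temporal and not cfg.uses_spatial
        if needs_static and static_adjacency is None:
            raise ConfigurationError(
                f"variant {cfg.variant!r} has no spatial attention and needs a "
                "static kNN adjacency"
            )
        self.static_mask = (
            np.asarray(static_adjacency, dtype=float) != 0.0
            if static_adjacency is not None else None
        )
        self.readout_drop = nn.Dropout(cfg.dropout)
        self.head = nn.Linear(readout_in, cfg.n_classes, rng)

    # -- forward pieces ----------------------------------------------------

    def encode(self, x: Tensor) -> Tensor:
        """Transformer learning block: conv stack (+ transformer encoder)."""
        xh = self.conv(x)
        if self.cfg.uses_transformer:
            b, n, c, t_r = xh.shape
            seq = xh.transpose(0, 1, 3, 2).reshape(b * n, t_r, c)
            seq = self.transformer(seq)
            xh = seq.reshape(b, n, t_r, c).transpose(0, 1, 3, 2)
        return xh

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        cfg = self.cfg
        xh = self.encode(x)
        b, n, c, t_r = xh.shape
        if not cfg.uses_gat:
            feats = xh.reshape(b, n, c * t_r)
            pooled = feats.mean(axis=1)
            return self.head(self.readout_drop(pooled))
        adjacency = None
        if cfg.uses_spatial:
            _, a_topk, keep = self.spatial(xh)
            adjacency, neighborhood = a_topk, keep
        else:
            neighborhood = self.static_mask
        if cfg.uses_temporal:
            xh = apply_temporal(self.temporal(xh), xh)
        node_feats = xh.reshape(b, n, c * t_r)
        gat_out = self.gat(node_feats, neighborhood, adjacency)
        pooled = gat_out.mean(axis=1)
        return self.head(self.readout_drop(pooled))

    def dynamic_adjacency(self, x, post_topk: bool = False) -> np.ndarray:
        """Per-sample learned adjacency (B x N x N) for analysis/visualization.

        By default returns the standardized pre-Top-K matrix; set
        ``post_topk=True`` for the sparsified one.
        """
        if not self.cfg.uses_spatial:
            raise ConfigurationError(
                f"variant {self.cfg.variant!r} has no spatial attention"
            )
        if not isinstance(x, Tensor):
            x = Tensor(x)
        a_std, a_topk, _ = self.spatial(self.encode(x))
        return (a_topk if post_topk else a_std).data.copy()
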