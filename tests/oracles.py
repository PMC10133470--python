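"""Independent naive-loop oracles used to cross-check the vectorized layers.

Everything here is deliberately written with explicit Python loops and plain
NumPy, sharing no code path with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def fft_bandpass(signal: np.ndarray, rate: float, low: float, high: float) -> np.ndarray:
    """Ideal (brick-wall) band-pass via FFT masking; reference for filtering."""
    spectrum = np.fft.rfft(signal, axis=-1)
    freqs = np.fft.rfftfreq(signal.shape[-1], d=1.0 / rate)
    mask = (freqs >= low) & (freqs <= high)
    return np.fft.irfft(spectrum * mask, signal.shape[-1], axis=-1)


def spatial_attention_scores(xh, v, w1, w2, b):
    """Nested-loop version of S = V tanh(W1 X_h W2 + b_s)."""
    bsz, n, c, t_r = xh.shape
    s = np.zeros((bsz, n, n))
    for bb in range(bsz):
        m1 = np.zeros((n, c))
        for i in range(n):
            for k in range(c):
                m1[i, k] = sum(xh[bb, i, k, t] * w1[t] for t in range(t_r))
        m2 = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                m2[i, j] = sum(m1[i, k] * w2[k, j] for k in range(c))
        inner = np.tanh(m2 + b)
        for i in range(n):
            for j in range(n):
                s[bb, i, j] = sum(v[i, k] * inner[k, j] for k in range(n))
    return s


def temporal_attention_scores(xh, v, u3, u4, b):
    """Nested-loop version of the temporal map on the transposed tensor."""
    bsz, n, c, t_r = xh.shape
    s = np.zeros((bsz, t_r, t_r))
    for bb in range(bsz):
        m1 = np.zeros((t_r, c))
        for t in range(t_r):
            for k in range(c):
                m1[t, k] = sum(xh[bb, i, k, t] * u3[i] for i in range(n))
        m2 = np.zeros((t_r, t_r))
        for t in range(t_r):
            for u in range(t_r):
                m2[t, u] = sum(m1[t, k] * u4[k, u] for k in range(c))
        inner = np.tanh(m2 + b)
        for t in range(t_r):
            for u in range(t_r):
                s[bb, t, u] = sum(v[t, k] * inner[k, u] for k in range(t_r))
    return s


def standardize(s, eps=1e-5):
    return (s - s.mean()) / np.sqrt(s.var() + eps)


def topk_rows(a, k):
    """Row-wise top-k keep with stable lower-index tie-break."""
    out = np.zeros_like(a)
    flat = a.reshape(-1, a.shape[-1])
    out_flat = out.reshape(-1, a.shape[-1])
    for r in range(flat.shape[0]):
        row = flat[r]
        if k >= row.size:
            out_flat[r] = row
            continue
        order = sorted(range(row.size), key=lambda j: (-row[j], j))
        for j in order[:k]:
            out_flat[r, j] = row[j]
    return out


def apply_temporal_loops(t_hat, xh):
    bsz, n, c, t_r = xh.shape
    out = np.zeros_like(xh)
    for bb in range(bsz):
        for i in range(n):
            for k in range(c):
                for t in range(t_r):
                    out[bb, i, k, t] = sum(
                        t_hat[bb, t, s] * xh[bb, i, k, s] for s in range(t_r)
                    )
    return out


def gat_forward_loops(h, mask, w, a_src, a_dst, adjacency=None, slope=0.2):
    """Double-loop multi-head GAT with self-loops and optional additive bias.

    ``h``: (B, N, F); ``mask``: (B, N, N) bool neighborhoods (without the
    self-loop); ``w``: (K, F, F'); ``a_src``/``a_dst``: (K, F').
    """
    bsz, n, _ = h.shape
    heads, _, f_out = w.shape
    out = np.zeros((bsz, n, f_out))
    for bb in range(bsz):
        acc = np.zeros((heads, n, f_out))
        for k in range(heads):
            wh = h[bb] @ w[k]  # (N, F')
            for i in range(n):
                neigh = [j for j in range(n) if mask[bb, i, j] or j == i]
                logits = []
                for j in neigh:
                    e = a_src[k] @ wh[i] + a_dst[k] @ wh[j]
                    e = e if e > 0 else slope * e
                    if adjacency is not None:
                        e = e + adjacency[bb, i, j]
                    logits.append(e)
                logits = np.array(logits)
                alpha = np.exp(logits - logits.max())
                alpha = alpha / alpha.sum()
                for a, j in zip(alpha, neigh):
                    acc[k, i] += a * wh[j]
        mean = acc.mean(axis=0)
        out[bb] = np.where(mean > 0, mean, np.exp(np.minimum(mean, 0.0)) - 1.0)
    return out


def transformer_layer_loops(x, layer):
    """Single-head pre-norm encoder layer computed with dense loops."""

    def layer_norm(v, gamma, beta, eps=1e-5):
        m = v.mean(axis=-1, keepdims=True)
        var = ((v - m) ** 2).mean(axis=-1, keepdims=True)
        return (v - m) / np.sqrt(var + eps) * gamma + beta

    bsz, seq, dim = x.shape
    out = np.zeros_like(x)
    for bb in range(bsz):
        z = layer_norm(x[bb], layer.ln1.gamma.data, layer.ln1.beta.data)
        q = z @ layer.attn.q.weight.data + layer.attn.q.bias.data
        k = z @ layer.attn.k.weight.data + layer.attn.k.bias.data
        v = z @ layer.attn.v.weight.data + layer.attn.v.bias.data
        scores = q @ k.T / np.sqrt(dim)
        att = np.exp(scores - scores.max(axis=-1, keepdims=True))
        att = att / att.sum(axis=-1, keepdims=True)
        attended = att @ v
        attended = attended @ layer.attn.out.weight.data + layer.attn.out.bias.data
        h = x[bb] + attended
        z2 = layer_norm(h, layer.ln2.gamma.data, layer.ln2.beta.data)
        ff = np.maximum(z2 @ layer.ff1.weight.data + layer.ff1.bias.data, 0.0)
        ff = ff @ layer.ff2.weight.data + layer.ff2.bias.data
        out[bb] = h + ff
    return out


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar-valued ``f`` at array ``x``."""
    grad = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
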