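"""A compact transformer encoder in numpy with exact manual backpropagation.

The relation classifier is the standard encoder architecture: summed token,
segment and position embeddings feed a stack of encoder layers (multi-head
scaled-dot-product self-attention and a ReLU feed-forward block, each with a
residual connection and layer normalisation), followed by a masked-mean
pooling, a tanh dense layer and a softmax classifier.  A parallel
masked-language-modelling head projects per-token hidden states back onto
the vocabulary for domain fine-tuning.

Everything is float64 and driven by seeded :class:`numpy.random.Generator`
instances, so training and inference are bit-deterministic for a given seed.
Gradients are derived by hand and verified against finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

Params = dict[str, np.ndarray]

_LN_EPS = 1e-5
_NEG_INF = -1e9


# ---------------------------------------------------------------------------
# initialisation

def init_params(
    num_layers: int,
    num_heads: int,
    hidden_dim: int,
    max_seq_len: int,
    vocab_size: int,
    num_classes: int,
    seed: int,
) -> Params:
    """Gaussian(0, 0.02) weights, zero biases, unit layer-norm gains."""
    if hidden_dim % num_heads:
        raise ValueError("hidden_dim must be divisible by num_heads")
    rng = np.random.default_rng(seed)
    d = hidden_dim

    def w(*shape):
        return rng.normal(0.0, 0.02, size=shape)

    p: Params = {
        "_num_heads": np.array(num_heads),
        "tok_emb": w(vocab_size, d),
        "seg_emb": w(2, d),
        "pos_emb": w(max_seq_len, d),
        "pool.w": w(d, d),
        "pool.b": np.zeros(d),
        "cls.w": w(d, num_classes),
        "cls.b": np.zeros(num_classes),
        "mlm.w": w(d, vocab_size),
        "mlm.b": np.zeros(vocab_size),
    }
    for i in range(num_layers):
        pre = f"l{i}."
        p[pre + "wq"] = w(d, d)
        p[pre + "bq"] = np.zeros(d)
        p[pre + "wk"] = w(d, d)
        p[pre + "bk"] = np.zeros(d)
        p[pre + "wv"] = w(d, d)
        p[pre + "bv"] = np.zeros(d)
        p[pre + "wo"] = w(d, d)
        p[pre + "bo"] = np.zeros(d)
        p[pre + "ln1.g"] = np.ones(d)
        p[pre + "ln1.b"] = np.zeros(d)
        p[pre + "w1"] = w(d, 4 * d)
        p[pre + "b1"] = np.zeros(4 * d)
        p[pre + "w2"] = w(4 * d, d)
        p[pre + "b2"] = np.zeros(d)
        p[pre + "ln2.g"] = np.ones(d)
        p[pre + "ln2.b"] = np.zeros(d)
    return p


def num_layers_of(params: Params) -> int:
    n = 0
    while f"l{n}.wq" in params:
        n += 1
    return n


# ---------------------------------------------------------------------------
# primitives

def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    std = np.sqrt(x.var(-1, keepdims=True) + _LN_EPS)
    xhat = (x - mu) / std
    return g * xhat + b, (xhat, std, g)


def _layernorm_bwd(dout, cache):
    xhat, std, g = cache
    dxhat = dout * g
    axes = tuple(range(dout.ndim - 1))
    dg = (dout * xhat).sum(axis=axes)
    db = dout.sum(axis=axes)
    dx = (dxhat - dxhat.mean(-1, keepdims=True) - xhat * (dxhat * xhat).mean(-1, keepdims=True)) / std
    return dx, dg, db


# ---------------------------------------------------------------------------
# encoder

def encoder_forward(
    params: Params,
    ids: np.ndarray,
    seg: np.ndarray,
    attn_mask: np.ndarray,
):
    """Run the encoder stack.

    ``ids``/``seg``/``attn_mask`` are (B, L) integer arrays; masked (pad)
    positions have ``attn_mask == 0`` and are excluded from attention.
    Returns the final hidden states (B, L, D) and a cache for backprop.
    """
    B, L = ids.shape
    x = params["tok_emb"][ids] + params["seg_emb"][seg] + params["pos_emb"][:L]
    mask_bias = (1.0 - attn_mask[:, None, None, :]) * _NEG_INF  # (B,1,1,L)
    caches = []
    n_layers = num_layers_of(params)
    heads = _infer_heads(params, n_layers)
    for i in range(n_layers):
        x, cache = _layer_fwd(params, f"l{i}.", x, heads, mask_bias)
        caches.append(cache)
    return x, {"ids": ids, "seg": seg, "layers": caches, "L": L, "heads": heads}


def _infer_heads(params: Params, n_layers: int) -> int:
    # head count is stored alongside the parameters by the caller
    return int(params.get("_num_heads", np.array(1)))


def _layer_fwd(p: Params, pre: str, x, H: int, mask_bias):
    B, L, D = x.shape
    Dh = D // H

    def heads_view(t):
        return t.reshape(B, L, H, Dh).transpose(0, 2, 1, 3)  # (B,H,L,Dh)

    q = heads_view(x @ p[pre + "wq"] + p[pre + "bq"])
    k = heads_view(x @ p[pre + "wk"] + p[pre + "bk"])
    v = heads_view(x @ p[pre + "wv"] + p[pre + "bv"])
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(Dh) + mask_bias
    att = softmax(scores)
    ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
    attn_out = ctx @ p[pre + "wo"] + p[pre + "bo"]
    r1 = x + attn_out
    n1, ln1_cache = _layernorm_fwd(r1, p[pre + "ln1.g"], p[pre + "ln1.b"])
    pre_act = n1 @ p[pre + "w1"] + p[pre + "b1"]
    h = np.maximum(pre_act, 0.0)
    ffn_out = h @ p[pre + "w2"] + p[pre + "b2"]
    r2 = n1 + ffn_out
    n2, ln2_cache = _layernorm_fwd(r2, p[pre + "ln2.g"], p[pre + "ln2.b"])
    cache = (x, q, k, v, att, ctx, n1, ln1_cache, pre_act, h, ln2_cache)
    return n2, cache


def _layer_bwd(p: Params, pre: str, dout, cache, grads: Params):
    x, q, k, v, att, ctx, n1, ln1_cache, pre_act, h, ln2_cache = cache
    B, L, D = x.shape
    H = q.shape[1]
    Dh = D // H

    dr2, dg2, db2 = _layernorm_bwd(dout, ln2_cache)
    grads[pre + "ln2.g"] = dg2
    grads[pre + "ln2.b"] = db2
    # r2 = n1 + ffn_out
    dffn = dr2
    dn1 = dr2.copy()
    flat_h = h.reshape(-1, h.shape[-1])
    grads[pre + "w2"] = flat_h.T @ dffn.reshape(-1, D)
    grads[pre + "b2"] = dffn.sum(axis=(0, 1))
    dh = dffn @ p[pre + "w2"].T
    dpre = dh * (pre_act > 0)
    grads[pre + "w1"] = n1.reshape(-1, D).T @ dpre.reshape(-1, 4 * D)
    grads[pre + "b1"] = dpre.sum(axis=(0, 1))
    dn1 += dpre @ p[pre + "w1"].T

    dr1, dg1, db1 = _layernorm_bwd(dn1, ln1_cache)
    grads[pre + "ln1.g"] = dg1
    grads[pre + "ln1.b"] = db1
    # r1 = x + attn_out
    dattn_out = dr1
    dx = dr1.copy()
    grads[pre + "wo"] = ctx.reshape(-1, D).T @ dattn_out.reshape(-1, D)
    grads[pre + "bo"] = dattn_out.sum(axis=(0, 1))
    dctx = (dattn_out @ p[pre + "wo"].T).reshape(B, L, H, Dh).transpose(0, 2, 1, 3)

    datt = dctx @ v.transpose(0, 1, 3, 2)          # (B,H,L,L)
    dv = att.transpose(0, 1, 3, 2) @ dctx          # (B,H,L,Dh)
    dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
    dscores /= np.sqrt(Dh)
    dq = dscores @ k
    dk = dscores.transpose(0, 1, 3, 2) @ q

    def flat(t):  # (B,H,L,Dh) -> (B*L, D)
        return t.transpose(0, 2, 1, 3).reshape(-1, D)

    xf = x.reshape(-1, D)
    for name, grad in (("wq", dq), ("wk", dk), ("wv", dv)):
        g = flat(grad)
        grads[pre + name] = xf.T @ g
        grads[pre + "b" + name[1]] = g.sum(axis=0)
        dx += (g @ p[pre + name].T).reshape(B, L, D)
    return dx


def encoder_backward(params: Params, cache, d_hidden) -> Params:
    """Backprop ``d_hidden`` (gradient w.r.t. final hidden states) through
    the stack and embeddings; returns gradients for every encoder weight."""
    grads: Params = {}
    dx = d_hidden
    for i in reversed(range(len(cache["layers"]))):
        dx = _layer_bwd(params, f"l{i}.", dx, cache["layers"][i], grads)
    ids, seg, L = cache["ids"], cache["seg"], cache["L"]
    dtok = np.zeros_like(params["tok_emb"])
    np.add.at(dtok, ids, dx)
    dseg = np.zeros_like(params["seg_emb"])
    np.add.at(dseg, seg, dx)
    dpos = np.zeros_like(params["pos_emb"])
    dpos[:L] = dx.sum(axis=0)
    grads["tok_emb"] = dtok
    grads["seg_emb"] = dseg
    grads["pos_emb"] = dpos
    return grads


# ---------------------------------------------------------------------------
# heads

def pooled_head_forward(params: Params, hidden, attn_mask):
    """Masked mean pooling -> tanh dense -> class logits."""
    m = attn_mask[..., None].astype(float)
    counts = m.sum(axis=1)
    pooled = (hidden * m).sum(axis=1) / counts
    z = pooled @ params["pool.w"] + params["pool.b"]
    act = np.tanh(z)
    logits = act @ params["cls.w"] + params["cls.b"]
    return logits, (m, counts, pooled, act)


def pooled_head_backward(params: Params, dlogits, cache, hidden_shape):
    m, counts, pooled, act = cache
    grads: Params = {
        "cls.w": act.T @ dlogits,
        "cls.b": dlogits.sum(axis=0),
    }
    dact = dlogits @ params["cls.w"].T
    dz = dact * (1.0 - act ** 2)
    grads["pool.w"] = pooled.T @ dz
    grads["pool.b"] = dz.sum(axis=0)
    dpooled = dz @ params["pool.w"].T
    d_hidden = (dpooled[:, None, :] / counts[:, None, :]) * m
    return grads, d_hidden


def mlm_head_forward(params: Params, hidden):
    return hidden @ params["mlm.w"] + params["mlm.b"]


def mlm_head_backward(params: Params, dlogits, hidden):
    D = hidden.shape[-1]
    grads: Params = {
        "mlm.w": hidden.reshape(-1, D).T @ dlogits.reshape(-1, dlogits.shape[-1]),
        "mlm.b": dlogits.sum(axis=(0, 1)),
    }
    d_hidden = dlogits @ params["mlm.w"].T
    return grads, d_hidden


# ---------------------------------------------------------------------------
# loss

def cross_entropy(logits, labels, class_weights: Optional[np.ndarray] = None):
    """Softmax cross-entropy; returns (loss, dlogits, probs).

    With ``class_weights`` (one per class, conventionally normalised to mean
    one) the per-example losses are weighted: equal weights reproduce the
    unweighted loss exactly.
    """
    n = len(labels)
    probs = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[labels]
    nll = -np.log(probs[np.arange(n), labels] + 1e-300)
    loss = float(np.mean(w * nll))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / n)[:, None]
    return loss, dlogits, probs


# ---------------------------------------------------------------------------
# optimisers

class Optimizer:
    """SGD, SGD-with-momentum (0.9) or Adam over a parameter dict."""

    def __init__(self, kind: str, lr: float):
        kind = kind.lower()
        if kind not in ("sgd", "momentum", "adam"):
            raise ValueError(f"unknown optimizer: {kind!r}")
        self.kind = kind
        self.lr = lr
        self.state: dict[str, dict[str, np.ndarray]] = {}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        for name, g in grads.items():
            if name.startswith("_"):
                continue
            p = params[name]
            if self.kind == "sgd":
                p -= self.lr * g
            elif self.kind == "momentum":
                st = self.state.setdefault(name, {"v": np.zeros_like(p)})
                st["v"] = 0.9 * st["v"] + g
                p -= self.lr * st["v"]
            else:  # adam
                st = self.state.setdefault(
                    name, {"m": np.zeros_like(p), "v": np.zeros_like(p)}
                )
                b1, b2, eps = 0.9, 0.999, 1e-8
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / (1 - b1 ** self.t)
                vhat = st["v"] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
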