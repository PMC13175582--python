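"""Minimal causal self-attention network with manual backpropagation.

This is the numerical engine behind the denoising trajectory autoencoder:
an input projection with sinusoidal positional encoding, a stack of
pre-softmax causally-masked multi-head attention blocks with post-layer-norm
residual feed-forward sublayers, and a linear reconstruction head.  The
causal mask guarantees that the hidden state at timestep t depends only on
timesteps <= t, so embeddings are honest at decision time.

Everything is plain float64 numpy.  Gradients are exact analytic
derivatives (verified against finite differences in the test suite), and
optimization uses Adam.  All shapes are (batch, time, channels); a boolean
``valid`` mask marks real (non-padding) timesteps, which are the only keys
attended to and the only positions contributing to the loss.
"""

from __future__ import annotations

import numpy as np

_NEG = -1e30
_LN_EPS = 1e-5


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def _layernorm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    dxhat = dy * g
    mean_dxhat = dxhat.mean(axis=-1, keepdims=True)
    mean_dxhat_xhat = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
    return dx, dg, db


class CausalEncoderNet:
    """Parameter container + forward/backward for the encoder network."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        d_model: int,
        n_layers: int,
        n_heads: int,
        ffn_factor: int = 4,
        seed: int = 0,
        max_len: int = 512,
    ) -> None:
        if d_model % n_heads:
            raise ValueError("n_heads must divide d_model")
        self.d_in, self.d_out, self.d_model = d_in, d_out, d_model
        self.n_layers, self.n_heads = n_layers, n_heads
        self.d_head = d_model // n_heads
        self.d_ffn = ffn_factor * d_model
        self.pos = sinusoidal_positions(max_len, d_model)
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-limit, limit, size=shape)

        p["W_in"] = glorot((d_in, d_model))
        p["b_in"] = np.zeros(d_model)
        for l in range(n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{name}{l}"] = glorot((d_model, d_model))
                p[f"{name[0]}b{name[1]}{l}"] = np.zeros(d_model)
            p[f"ln1_g{l}"] = np.ones(d_model)
            p[f"ln1_b{l}"] = np.zeros(d_model)
            p[f"W1{l}"] = glorot((d_model, self.d_ffn))
            p[f"c1{l}"] = np.zeros(self.d_ffn)
            p[f"W2{l}"] = glorot((self.d_ffn, d_model))
            p[f"c2{l}"] = np.zeros(d_model)
            p[f"ln2_g{l}"] = np.ones(d_model)
            p[f"ln2_b{l}"] = np.zeros(d_model)
        p["W_out"] = glorot((d_model, d_out))
        p["b_out"] = np.zeros(d_out)
        self.params = p

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, valid: np.ndarray):
        """Return (out, hidden, cache); X is (B, T, d_in), valid is (B, T)."""
        p = self.params
        B, T, _ = X.shape
        H, dh = self.n_heads, self.d_head
        x = X @ p["W_in"] + p["b_in"] + self.pos[:T]
        cache: dict = {"X": X, "valid": valid, "layers": []}

        causal = np.tril(np.ones((T, T), dtype=bool))
        key_mask = valid[:, None, None, :] & causal[None, None, :, :]

        for l in range(self.n_layers):
            lc: dict = {"x_in": x}
            q = x @ p[f"Wq{l}"] + p[f"Wbq{l}"]
            k = x @ p[f"Wk{l}"] + p[f"Wbk{l}"]
            v = x @ p[f"Wv{l}"] + p[f"Wbv{l}"]

            def split(z):
                return z.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

            qh, kh, vh = split(q), split(k), split(v)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
            scores = np.where(key_mask, scores, _NEG)
            scores -= scores.max(axis=-1, keepdims=True)
            exps = np.exp(scores)
            attn = exps / exps.sum(axis=-1, keepdims=True)
            ctx = attn @ vh  # (B,H,T,dh)
            ctx_merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
            attn_out = ctx_merged @ p[f"Wo{l}"] + p[f"Wbo{l}"]
            lc.update(qh=qh, kh=kh, vh=vh, attn=attn, ctx_merged=ctx_merged)

            res1 = x + attn_out
            x, lc["ln1"] = _layernorm_forward(res1, p[f"ln1_g{l}"], p[f"ln1_b{l}"])
            lc["x_mid"] = x
            pre = x @ p[f"W1{l}"] + p[f"c1{l}"]
            act = np.maximum(pre, 0.0)
            ffn = act @ p[f"W2{l}"] + p[f"c2{l}"]
            lc.update(pre=pre, act=act)
            res2 = x + ffn
            x, lc["ln2"] = _layernorm_forward(res2, p[f"ln2_g{l}"], p[f"ln2_b{l}"])
            cache["layers"].append(lc)

        out = x @ p["W_out"] + p["b_out"]
        cache["hidden"] = x
        return out, x, cache

    # -- backward ---------------------------------------------------------

    def backward(self, dout: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(out)."""
        p = self.params
        X, valid = cache["X"], cache["valid"]
        B, T, _ = X.shape
        H, dh = self.n_heads, self.d_head
        g: dict[str, np.ndarray] = {}

        hidden = cache["hidden"]
        g["W_out"] = hidden.reshape(-1, self.d_model).T @ dout.reshape(-1, self.d_out)
        g["b_out"] = dout.sum(axis=(0, 1))
        dx = dout @ p["W_out"].T

        for l in reversed(range(self.n_layers)):
            lc = cache["layers"][l]
            # second layer norm
            dres2, g[f"ln2_g{l}"], g[f"ln2_b{l}"] = _layernorm_backward(dx, lc["ln2"])
            dffn = dres2
            dx_mid = dres2.copy()
            # ffn
            g[f"W2{l}"] = (
                lc["act"].reshape(-1, self.d_ffn).T
                @ dffn.reshape(-1, self.d_model)
            )
            g[f"c2{l}"] = dffn.sum(axis=(0, 1))
            dact = dffn @ p[f"W2{l}"].T
            dpre = dact * (lc["pre"] > 0)
            g[f"W1{l}"] = (
                lc["x_mid"].reshape(-1, self.d_model).T
                @ dpre.reshape(-1, self.d_ffn)
            )
            g[f"c1{l}"] = dpre.sum(axis=(0, 1))
            dx_mid += dpre @ p[f"W1{l}"].T
            # first layer norm
            dres1, g[f"ln1_g{l}"], g[f"ln1_b{l}"] = _layernorm_backward(
                dx_mid, lc["ln1"]
            )
            dattn_out = dres1
            dx = dres1.copy()
            # attention output projection
            g[f"Wo{l}"] = (
                lc["ctx_merged"].reshape(-1, self.d_model).T
                @ dattn_out.reshape(-1, self.d_model)
            )
            g[f"Wbo{l}"] = dattn_out.sum(axis=(0, 1))
            dctx_merged = dattn_out @ p[f"Wo{l}"].T
            dctx = dctx_merged.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            attn, qh, kh, vh = lc["attn"], lc["qh"], lc["kh"], lc["vh"]
            dvh = attn.transpose(0, 1, 3, 2) @ dctx
            dattn = dctx @ vh.transpose(0, 1, 3, 2)
            dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            dqh = dscores @ kh / np.sqrt(dh)
            dkh = dscores.transpose(0, 1, 3, 2) @ qh / np.sqrt(dh)

            def merge(z):
                return z.transpose(0, 2, 1, 3).reshape(B, T, self.d_model)

            dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
            x_in = lc["x_in"]
            flat = x_in.reshape(-1, self.d_model).T
            g[f"Wq{l}"] = flat @ dq.reshape(-1, self.d_model)
            g[f"Wk{l}"] = flat @ dk.reshape(-1, self.d_model)
            g[f"Wv{l}"] = flat @ dv.reshape(-1, self.d_model)
            g[f"Wbq{l}"] = dq.sum(axis=(0, 1))
            g[f"Wbk{l}"] = dk.sum(axis=(0, 1))
            g[f"Wbv{l}"] = dv.sum(axis=(0, 1))
            dx += dq @ p[f"Wq{l}"].T + dk @ p[f"Wk{l}"].T + dv @ p[f"Wv{l}"].T

        g["W_in"] = X.reshape(-1, self.d_in).T @ dx.reshape(-1, self.d_model)
        g["b_in"] = dx.sum(axis=(0, 1))
        return g

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def reconstruction_loss_and_grad(
    out: np.ndarray,
    target_cont: np.ndarray,
    target_flags: np.ndarray,
    valid: np.ndarray,
    n_cont: int,
):
    """Masked MSE on continuous channels + BCE-with-logits on flag channels.

    Returns (total loss, mse part, d(loss)/d(out)).
    """
    mask = valid[:, :, None].astype(float)
    n_valid = max(valid.sum(), 1)
    out_c = out[:, :, :n_cont]
    diff = (out_c - target_cont) * mask
    mse = float((diff**2).sum() / (n_valid * n_cont))

    dout = np.zeros_like(out)
    dout[:, :, :n_cont] = 2.0 * diff / (n_valid * n_cont)

    n_flags = out.shape[-1] - n_cont
    bce = 0.0
    if n_flags:
        logits = out[:, :, n_cont:]
        probs = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        bce_terms = -(
            target_flags * np.log(probs + eps)
            + (1 - target_flags) * np.log(1 - probs + eps)
        ) * mask
        bce = float(bce_terms.sum() / (n_valid * n_flags))
        dout[:, :, n_cont:] = (probs - target_flags) * mask / (n_valid * n_flags)
    return mse + bce, mse, dout
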