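"""Decoder-only transformer language model, implemented in NumPy.

Architecture: token embedding, a stack of pre-LayerNorm transformer blocks
with causal multi-head attention under rotary position embeddings (RoPE)
and a SwiGLU feedforward, a final LayerNorm, and an untied linear output
head. There is no learned positional table — all positional information
enters through the rotation of query/key vectors — and no biases on the
attention or feedforward projections.

Both the forward pass and the exact backward pass are written by hand in
NumPy (float64 throughout), which keeps the package self-contained and
makes the gradients directly checkable against finite differences. The
intended scale is desk scale: configurations of a few layers and widths of
64-256 train in seconds on one CPU. The full-size configuration (12
layers, 14 heads, width 896) instantiates and counts correctly but is not
meant to be trained here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


@dataclass
class ModelConfig:
    """Hyperparameters of the decoder transformer.

    ``ffn_hidden`` is derived from ``ffn_ratio * d_model`` rounded to the
    nearest multiple of 64 (never below ``d_model``); SwiGLU counts three
    projection matrices (gate, up, down) at that width.
    """

    n_layers: int = 12
    n_heads: int = 14
    d_model: int = 896
    ffn_ratio: float = 8 / 3
    vocab_size: int = 27
    max_len: int = 512
    tie_embeddings: bool = False
    rope_base: float = 10_000.0
    dtype: str = "float64"  # float32 halves memory traffic for desk training

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.head_dim % 2 != 0:
            raise ValueError("head dimension must be even for RoPE")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def ffn_hidden(self) -> int:
        raw = self.ffn_ratio * self.d_model
        rounded = int(round(raw / 64.0)) * 64
        return max(rounded, self.d_model)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(tuple(range(dy.ndim - 1)))
    db = dy.sum(tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = dxhat.mean(-1, keepdims=True)
    mx = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def _rope_tables(positions: np.ndarray, head_dim: int, base: float):
    """cos/sin tables of shape (len(positions), head_dim/2)."""
    inv_freq = base ** (-np.arange(0, head_dim, 2, dtype=float) / head_dim)
    ang = positions[:, None] * inv_freq[None, :]
    return np.cos(ang), np.sin(ang)


def _rope_apply(x: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> np.ndarray:
    """Rotate interleaved (even, odd) channel pairs; x is (..., T, head_dim)."""
    x1, x2 = x[..., 0::2], x[..., 1::2]
    out = np.empty_like(x)
    out[..., 0::2] = x1 * cos - x2 * sin
    out[..., 1::2] = x1 * sin + x2 * cos
    return out


def _rope_unapply(d: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> np.ndarray:
    # transpose of the rotation = rotation by -angle
    d1, d2 = d[..., 0::2], d[..., 1::2]
    out = np.empty_like(d)
    out[..., 0::2] = d1 * cos + d2 * sin
    out[..., 1::2] = -d1 * sin + d2 * cos
    return out


class DecoderLM:
    """A causal language model with explicit forward/backward in NumPy.

    Parameters live in ``self.params`` (name -> float64 array). ``forward``
    returns logits and, optionally, the activation cache consumed by
    ``backward``; ``step`` runs one incremental decoding step against a
    key/value cache for fast sampling.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.params = self._init_params(seed)

    # -- initialization ----------------------------------------------------

    def _init_params(self, seed: int) -> Params:
        cfg = self.config
        rng = np.random.default_rng(seed)
        std = 0.02
        p: Params = {}
        dt = np.dtype(cfg.dtype)
        p["embed"] = rng.normal(0.0, std, (cfg.vocab_size, cfg.d_model))
        for i in range(cfg.n_layers):
            pre = f"l{i}."
            for w in ("wq", "wk", "wv", "wo"):
                p[pre + w] = rng.normal(0.0, std, (cfg.d_model, cfg.d_model))
            p[pre + "wg"] = rng.normal(0.0, std, (cfg.d_model, cfg.ffn_hidden))
            p[pre + "wu"] = rng.normal(0.0, std, (cfg.d_model, cfg.ffn_hidden))
            p[pre + "wd"] = rng.normal(0.0, std, (cfg.ffn_hidden, cfg.d_model))
            p[pre + "ln1.g"] = np.ones(cfg.d_model)
            p[pre + "ln1.b"] = np.zeros(cfg.d_model)
            p[pre + "ln2.g"] = np.ones(cfg.d_model)
            p[pre + "ln2.b"] = np.zeros(cfg.d_model)
        p["lnf.g"] = np.ones(cfg.d_model)
        p["lnf.b"] = np.zeros(cfg.d_model)
        if not cfg.tie_embeddings:
            p["head"] = rng.normal(0.0, std, (cfg.vocab_size, cfg.d_model))
        return {k: v.astype(dt) for k, v in p.items()}

    @property
    def head_weight(self) -> np.ndarray:
        return self.params["embed"] if self.config.tie_embeddings else self.params["head"]

    # -- forward -----------------------------------------------------------

    def forward(self, ids: np.ndarray, want_cache: bool = False):
        """Compute logits for every position of a (B, T) id batch.

        Returns ``logits`` of shape (B, T, vocab) — the logit at position t
        scores the token at position t+1 — and the activation cache when
        ``want_cache`` is set.
        """
        cfg = self.config
        p = self.params
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, T = ids.shape
        if T > cfg.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len={cfg.max_len}")
        H, hd = cfg.n_heads, cfg.head_dim
        dt = np.dtype(cfg.dtype)
        cos, sin = _rope_tables(np.arange(T, dtype=float), hd, cfg.rope_base)
        cos, sin = cos.astype(dt), sin.astype(dt)
        causal = np.triu(np.full((T, T), -np.inf), k=1).astype(dt)

        x = p["embed"][ids]  # (B, T, D)
        cache: dict = {"ids": ids, "cos": cos, "sin": sin, "layers": []}
        for i in range(cfg.n_layers):
            pre = f"l{i}."
            lc: dict = {"x_in": x}
            y, lc["ln1"] = _layer_norm(x, p[pre + "ln1.g"], p[pre + "ln1.b"])
            lc["y1"] = y
            q = (y @ p[pre + "wq"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            k = (y @ p[pre + "wk"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            v = (y @ p[pre + "wv"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            q = _rope_apply(q, cos, sin)
            k = _rope_apply(k, cos, sin)
            scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(hd) + causal
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            attn = e / e.sum(-1, keepdims=True)
            ctx = attn @ v  # (B, H, T, hd)
            lc.update(q=q, k=k, v=v, attn=attn)
            concat = ctx.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            lc["concat"] = concat
            x = x + concat @ p[pre + "wo"]

            lc["x_mid"] = x
            y2, lc["ln2"] = _layer_norm(x, p[pre + "ln2.g"], p[pre + "ln2.b"])
            lc["y2"] = y2
            gpre = y2 @ p[pre + "wg"]
            u = y2 @ p[pre + "wu"]
            h = _silu(gpre) * u
            lc.update(gpre=gpre, u=u, h=h)
            x = x + h @ p[pre + "wd"]
            cache["layers"].append(lc)

        cache["x_final"] = x
        yf, cache["lnf"] = _layer_norm(x, p["lnf.g"], p["lnf.b"])
        cache["yf"] = yf
        logits = yf @ self.head_weight.T
        if want_cache:
            return logits, cache
        return logits

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> Params:
        """Exact gradients of a scalar loss w.r.t. every parameter.

        ``dlogits`` is d(loss)/d(logits) with the same shape forward
        produced. Returns a dict keyed like ``self.params``.
        """
        cfg = self.config
        p = self.params
        ids = cache["ids"]
        B, T = ids.shape
        H, hd = cfg.n_heads, cfg.head_dim
        cos, sin = cache["cos"], cache["sin"]
        grads: Params = {k: np.zeros_like(v) for k, v in p.items()}

        head_key = "embed" if cfg.tie_embeddings else "head"
        grads[head_key] += dlogits.reshape(-1, cfg.vocab_size).T @ cache["yf"].reshape(
            -1, cfg.d_model
        )
        dyf = dlogits @ self.head_weight
        dx, dg, db = _layer_norm_backward(dyf, cache["lnf"], p["lnf.g"])
        grads["lnf.g"] += dg
        grads["lnf.b"] += db

        for i in reversed(range(cfg.n_layers)):
            pre = f"l{i}."
            lc = cache["layers"][i]
            # FFN branch
            dh = dx @ p[pre + "wd"].T
            grads[pre + "wd"] += lc["h"].reshape(-1, cfg.ffn_hidden).T @ dx.reshape(
                -1, cfg.d_model
            )
            dgpre = dh * lc["u"] * _silu_grad(lc["gpre"])
            du = dh * _silu(lc["gpre"])
            dy2 = dgpre @ p[pre + "wg"].T + du @ p[pre + "wu"].T
            y2flat = lc["y2"].reshape(-1, cfg.d_model)
            grads[pre + "wg"] += y2flat.T @ dgpre.reshape(-1, cfg.ffn_hidden)
            grads[pre + "wu"] += y2flat.T @ du.reshape(-1, cfg.ffn_hidden)
            dxm, dg, db = _layer_norm_backward(dy2, lc["ln2"], p[pre + "ln2.g"])
            grads[pre + "ln2.g"] += dg
            grads[pre + "ln2.b"] += db
            dx = dx + dxm  # residual

            # attention branch
            dconcat = dx @ p[pre + "wo"].T
            grads[pre + "wo"] += lc["concat"].reshape(-1, cfg.d_model).T @ dx.reshape(
                -1, cfg.d_model
            )
            dctx = dconcat.reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            attn, q, k, v = lc["attn"], lc["q"], lc["k"], lc["v"]
            dattn = dctx @ v.transpose(0, 1, 3, 2)
            dv = attn.transpose(0, 1, 3, 2) @ dctx
            dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
            dscores /= np.sqrt(hd)
            dq = dscores @ k
            dk = dscores.transpose(0, 1, 3, 2) @ q
            dq = _rope_unapply(dq, cos, sin)
            dk = _rope_unapply(dk, cos, sin)
            dq = dq.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            dk = dk.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            dv = dv.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            y1flat = lc["y1"].reshape(-1, cfg.d_model)
            grads[pre + "wq"] += y1flat.T @ dq.reshape(-1, cfg.d_model)
            grads[pre + "wk"] += y1flat.T @ dk.reshape(-1, cfg.d_model)
            grads[pre + "wv"] += y1flat.T @ dv.reshape(-1, cfg.d_model)
            dy1 = dq @ p[pre + "wq"].T + dk @ p[pre + "wk"].T + dv @ p[pre + "wv"].T
            dxa, dg, db = _layer_norm_backward(dy1, lc["ln1"], p[pre + "ln1.g"])
            grads[pre + "ln1.g"] += dg
            grads[pre + "ln1.b"] += db
            dx = dx + dxa  # residual

        np.add.at(grads["embed"], ids.reshape(-1), dx.reshape(-1, cfg.d_model))
        return grads

    # -- incremental decoding ----------------------------------------------

    def init_kv_cache(self, batch: int, max_len: Optional[int] = None) -> dict:
        cfg = self.config
        L = max_len or cfg.max_len
        dt = np.dtype(cfg.dtype)
        return {
            "k": np.zeros((cfg.n_layers, batch, cfg.n_heads, L, cfg.head_dim), dtype=dt),
            "v": np.zeros((cfg.n_layers, batch, cfg.n_heads, L, cfg.head_dim), dtype=dt),
            "len": 0,
        }

    def step(self, ids_t: np.ndarray, kv: dict) -> np.ndarray:
        """One decoding step: append token ids_t (B,) and return (B, vocab) logits."""
        cfg = self.config
        p = self.params
        B = ids_t.shape[0]
        H, hd = cfg.n_heads, cfg.head_dim
        t = kv["len"]
        dt = np.dtype(cfg.dtype)
        cos, sin = _rope_tables(np.array([float(t)]), hd, cfg.rope_base)
        cos, sin = cos.astype(dt), sin.astype(dt)
        x = p["embed"][ids_t]  # (B, D)
        for i in range(cfg.n_layers):
            pre = f"l{i}."
            y, _ = _layer_norm(x, p[pre + "ln1.g"], p[pre + "ln1.b"])
            q = (y @ p[pre + "wq"]).reshape(B, H, hd)
            k = (y @ p[pre + "wk"]).reshape(B, H, hd)
            v = (y @ p[pre + "wv"]).reshape(B, H, hd)
            q = _rope_apply(q[:, :, None, :], cos, sin)[:, :, 0, :]
            k = _rope_apply(k[:, :, None, :], cos, sin)[:, :, 0, :]
            kv["k"][i, :, :, t] = k
            kv["v"][i, :, :, t] = v
            K = kv["k"][i, :, :, : t + 1]  # (B, H, t+1, hd)
            V = kv["v"][i, :, :, : t + 1]
            scores = np.einsum("bhd,bhtd->bht", q, K) / np.sqrt(hd)
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            attn = e / e.sum(-1, keepdims=True)
            ctx = np.einsum("bht,bhtd->bhd", attn, V).reshape(B, cfg.d_model)
            x = x + ctx @ p[pre + "wo"]
            y2, _ = _layer_norm(x, p[pre + "ln2.g"], p[pre + "ln2.b"])
            h = _silu(y2 @ p[pre + "wg"]) * (y2 @ p[pre + "wu"])
            x = x + h @ p[pre + "wd"]
        yf, _ = _layer_norm(x, p["lnf.g"], p["lnf.b"])
        kv["len"] = t + 1
        return yf @ self.head_weight.T

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) with a JSON config side-car (.json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DecoderLM":
        path = Path(path)
        cfg = ModelConfig.from_json(path.with_suffix(".json").read_text())
        model = cls(cfg, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k].astype(cfg.dtype) for k in data.files}
        return model

    def clone(self) -> "DecoderLM":
        other = DecoderLM.__new__(DecoderLM)
        other.config = self.config
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other


def count_parameters(model: DecoderLM, breakdown: bool = False):
    """Exact count of trainable scalars, optionally itemized by group.

    The itemization distinguishes embedding, attention, feedforward,
    normalization and output-head weights so that the total can be audited
    shape by shape.
    """
    groups = {"embedding": 0, "attention": 0, "feedforward": 0, "norm": 0, "head": 0}
    for name, arr in model.params.items():
        if name == "embed":
            groups["embedding"] += arr.size
        elif name == "head":
            groups["head"] += arr.size
        elif ".ln" in name or name.startswith("lnf"):
            groups["norm"] += arr.size
        elif any(name.endswith(s) for s in ("wq", "wk", "wv", "wo")):
            groups["attention"] += arr.size
        else:
            groups["feedforward"] += arr.size
    total = sum(groups.values())
    if breakdown:
        return total, groups
    return total


def next_token_loss(
    logits: np.ndarray,
    targets: np.ndarray,
    ignore: Iterable[int] = (),
    return_grad: bool = False,
):
    """Mean next-token cross-entropy, excluding ignored target positions.

    ``logits`` and ``targets`` are aligned: the logit vector at position t
    scores the target token at position t (the caller shifts). Positions
    whose target id is in ``ignore`` (pad, reserved mask) contribute
    nothing and are excluded from the mean; if everything is ignored the
    mean is undefined and an error is raised. With ``return_grad`` the
    d(loss)/d(logits) array is returned as well.
    """
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(targets)
    flat = logits.reshape(-1, logits.shape[-1])
    tflat = targets.reshape(-1)
    ignore_ids = list(ignore)
    keep = (
        ~np.isin(tflat, ignore_ids) if ignore_ids else np.ones(tflat.shape, dtype=bool)
    )
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("all target positions are ignored; mean loss undefined")
    m = flat.max(-1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(flat - m).sum(-1))
    picked = flat[np.arange(flat.shape[0]), tflat]
    losses = np.where(keep, lse - picked, 0.0)
    loss = losses.sum() / n_keep
    if not return_grad:
        return loss
    probs = np.exp(flat - lse[:, None])
    dflat = probs
    dflat[np.arange(flat.shape[0]), tflat] -= 1.0
    dflat *= keep[:, None] / n_keep
    return loss, dflat.reshape(logits.shape)
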