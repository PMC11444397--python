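"""Causal decoder language model in numpy with handwritten backpropagation.

A pre-normalization transformer of the GPT-2 lineage: learned absolute
positional embeddings, multi-head causal self-attention, GELU feed-forward
blocks, and an output projection tied to the token embedding. Linear-layer
weights use Kaiming (He) initialization; embeddings are Gaussian with
standard deviation ``init_std`` (default 0.02); layer-norm gains start at 1.

All probabilities are natural-log. The forward pass keeps the caches needed
for the analytic backward pass used by the trainer; gradients are verified
against numerical differentiation in the test suite.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

__all__ = [
    "ModelConfig",
    "LanguageModel",
    "build_model",
    "count_parameters",
    "forward_logprobs",
    "sequence_nll",
    "NLLResult",
    "FULL_SCALE_PRESET",
    "DESK_PRESET",
]

_LN_EPS = 1e-5
_NEG_INF = -1e30


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int
    d_model: int
    n_heads: int
    context_len: int
    vocab_size: int
    init_std: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.context_len < 2:
            raise ValueError("context_len must be >= 2")
        if min(self.n_layers, self.d_model, self.n_heads, self.vocab_size) < 1:
            raise ValueError("n_layers, d_model, n_heads, vocab_size must be positive")


def DESK_PRESET(vocab_size: int, seed: int = 0, context_len: int = 256) -> ModelConfig:
    """Default desk-scale configuration used throughout tests and demos."""
    return ModelConfig(
        n_layers=4, d_model=128, n_heads=4, context_len=context_len,
        vocab_size=vocab_size, seed=seed,
    )


# Recorded for reference only: the published full-scale configuration
# (24 layers, width 1280, context 1024, vocabulary 1024). Never instantiated
# in the test suite; the method, not the scale, is the artifact here.
FULL_SCALE_PRESET = ModelConfig(
    n_layers=24, d_model=1280, n_heads=20, context_len=1024, vocab_size=1024
)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * phi


def _ln_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LanguageModel:
    """Config plus learned weights; emits next-token log-probability rows."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # ------------------------------------------------------------------ fwd
    def forward(self, ids: np.ndarray, with_cache: bool = False):
        """Logits for a batch of token-id rows; shape (B, L, V).

        Position t's logits depend only on positions <= t (causal masking).
        """
        cfg = self.config
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, L = ids.shape
        if L < 1 or L > cfg.context_len:
            raise ValueError(f"sequence length {L} outside 1..{cfg.context_len}")
        if ids.min() < 0 or ids.max() >= cfg.vocab_size:
            raise ValueError("token id outside vocabulary")
        p = self.params
        x = p["tok_emb"][ids] + p["pos_emb"][:L]
        causal = np.triu(np.full((L, L), _NEG_INF), k=1)
        layer_caches = []
        for li in range(cfg.n_layers):
            pre = f"l{li}."
            h1, ln1c = _ln_forward(x, p[pre + "ln1.g"], p[pre + "ln1.b"])
            ay, attnc = self._attn_forward(h1, li, causal)
            x = x + ay
            h2, ln2c = _ln_forward(x, p[pre + "ln2.g"], p[pre + "ln2.b"])
            my, mlpc = self._mlp_forward(h2, li)
            x = x + my
            layer_caches.append((h1, ln1c, attnc, h2, ln2c, mlpc))
        hf, lnfc = _ln_forward(x, p["ln_f.g"], p["ln_f.b"])
        logits = hf @ p["tok_emb"].T
        if with_cache:
            return logits, (ids, layer_caches, hf, lnfc)
        return logits

    def _attn_forward(self, x, li, causal):
        cfg = self.config
        p = self.params
        pre = f"l{li}.attn."
        B, L, d = x.shape
        h, dh = cfg.n_heads, d // cfg.n_heads
        qkv = x @ p[pre + "wqkv"] + p[pre + "bqkv"]
        q, k, v = np.split(qkv, 3, axis=-1)

        def heads(a):
            return a.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = heads(q), heads(k), heads(v)
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh) + causal
        att = _softmax(scores)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        y = out @ p[pre + "wo"] + p[pre + "bo"]
        return y, (x, q, k, v, att, out)

    def _mlp_forward(self, x, li):
        p = self.params
        pre = f"l{li}.mlp."
        z = x @ p[pre + "w1"] + p[pre + "b1"]
        a = _gelu(z)
        y = a @ p[pre + "w2"] + p[pre + "b2"]
        return y, (x, z, a)

    # ------------------------------------------------------------- loss/bwd
    def loss_and_grads(self, x_ids: np.ndarray, y_ids: np.ndarray, mask: np.ndarray):
        """Mean per-token NLL over masked positions, with analytic gradients."""
        cfg = self.config
        p = self.params
        logits, (ids, layer_caches, hf, lnfc) = self.forward(x_ids, with_cache=True)
        B, L, V = logits.shape
        y_ids = np.asarray(y_ids).reshape(B, L)
        mask = np.asarray(mask, dtype=float).reshape(B, L)
        n_tok = mask.sum()
        if n_tok == 0:
            raise ValueError("loss mask selects no tokens")
        logz = np.log(np.exp(logits - logits.max(-1, keepdims=True)).sum(-1, keepdims=True)) \
            + logits.max(-1, keepdims=True)
        logprobs = logits - logz
        gathered = np.take_along_axis(logprobs, y_ids[..., None], axis=-1)[..., 0]
        loss = -(gathered * mask).sum() / n_tok

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = np.exp(logprobs)
        np.add.at(dlogits.reshape(-1, V), (np.arange(B * L), y_ids.reshape(-1)), -1.0)
        dlogits *= (mask / n_tok)[..., None]

        grads["tok_emb"] += dlogits.reshape(-1, V).T @ hf.reshape(-1, cfg.d_model)
        dhf = dlogits @ p["tok_emb"]
        dx, dg, db = _ln_backward(dhf, lnfc)
        grads["ln_f.g"] += dg
        grads["ln_f.b"] += db

        for li in reversed(range(cfg.n_layers)):
            pre = f"l{li}."
            h1, ln1c, attnc, h2, ln2c, mlpc = layer_caches[li]
            # mlp residual branch
            dmy = dx
            dh2 = self._mlp_backward(dmy, li, mlpc, grads)
            dln2, dg2, db2 = _ln_backward(dh2, ln2c)
            grads[pre + "ln2.g"] += dg2
            grads[pre + "ln2.b"] += db2
            dx = dx + dln2
            # attention residual branch
            day = dx
            dh1 = self._attn_backward(day, li, attnc, grads)
            dln1, dg1, db1 = _ln_backward(dh1, ln1c)
            grads[pre + "ln1.g"] += dg1
            grads[pre + "ln1.b"] += db1
            dx = dx + dln1

        np.add.at(grads["tok_emb"], ids.reshape(-1), dx.reshape(-1, cfg.d_model))
        grads["pos_emb"][:L] += dx.sum(axis=0)
        return loss, grads

    def _mlp_backward(self, dy, li, cache, grads):
        p = self.params
        pre = f"l{li}.mlp."
        x, z, a = cache
        d_in = x.shape[-1]
        d_hid = z.shape[-1]
        dy2, a2 = dy.reshape(-1, d_in), a.reshape(-1, d_hid)
        grads[pre + "w2"] += a2.T @ dy2
        grads[pre + "b2"] += dy2.sum(axis=0)
        da = dy @ p[pre + "w2"].T
        dz = da * _gelu_grad(z)
        x2, dz2 = x.reshape(-1, d_in), dz.reshape(-1, d_hid)
        grads[pre + "w1"] += x2.T @ dz2
        grads[pre + "b1"] += dz2.sum(axis=0)
        return dz @ p[pre + "w1"].T

    def _attn_backward(self, dy, li, cache, grads):
        cfg = self.config
        p = self.params
        pre = f"l{li}.attn."
        x, q, k, v, att, out = cache
        B, L, d = x.shape
        h, dh = cfg.n_heads, d // cfg.n_heads
        dy2 = dy.reshape(-1, d)
        grads[pre + "wo"] += out.reshape(-1, d).T @ dy2
        grads[pre + "bo"] += dy2.sum(axis=0)
        dout = (dy @ p[pre + "wo"].T).reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        datt = dout @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dout
        dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dscores /= math.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q

        def merge(a):
            return a.transpose(0, 2, 1, 3).reshape(B, L, d)

        dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
        grads[pre + "wqkv"] += x.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
        grads[pre + "bqkv"] += dqkv.reshape(-1, 3 * d).sum(axis=0)
        return dqkv @ p[pre + "wqkv"].T

    # -------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        """Checkpoint: config JSON + flat weight archive in one npz file."""
        payload = {f"param/{k}": v for k, v in self.params.items()}
        payload["config_json"] = np.array(json.dumps(asdict(self.config)))
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "LanguageModel":
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig(**json.loads(str(z["config_json"])))
            params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        expected = set(_param_shapes(config))
        if set(params) != expected:
            raise ValueError("checkpoint weight manifest does not match config")
        for name, shape in _param_shapes(config).items():
            if params[name].shape != shape:
                raise ValueError(f"checkpoint weight {name} has shape {params[name].shape}, expected {shape}")
        return cls(config, params)

    def copy(self) -> "LanguageModel":
        return LanguageModel(self.config, {k: v.copy() for k, v in self.params.items()})


def _param_shapes(cfg: ModelConfig) -> dict[str, tuple[int, ...]]:
    d, v = cfg.d_model, cfg.vocab_size
    shapes: dict[str, tuple[int, ...]] = {
        "tok_emb": (v, d),
        "pos_emb": (cfg.context_len, d),
        "ln_f.g": (d,),
        "ln_f.b": (d,),
    }
    for li in range(cfg.n_layers):
        pre = f"l{li}."
        shapes[pre + "ln1.g"] = (d,)
        shapes[pre + "ln1.b"] = (d,)
        shapes[pre + "attn.wqkv"] = (d, 3 * d)
        shapes[pre + "attn.bqkv"] = (3 * d,)
        shapes[pre + "attn.wo"] = (d, d)
        shapes[pre + "attn.bo"] = (d,)
        shapes[pre + "ln2.g"] = (d,)
        shapes[pre + "ln2.b"] = (d,)
        shapes[pre + "mlp.w1"] = (d, 4 * d)
        shapes[pre + "mlp.b1"] = (4 * d,)
        shapes[pre + "mlp.w2"] = (4 * d, d)
        shapes[pre + "mlp.b2"] = (d,)
    return shapes


def build_model(config: ModelConfig) -> LanguageModel:
    """Initialize weights deterministically from ``config.seed``.

    Linear (matmul) weights: Kaiming normal, std = sqrt(2 / fan_in).
    Embeddings: Gaussian(0, init_std). Biases 0; layer-norm gain 1, bias 0.
    """
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    for name, shape in _param_shapes(config).items():
        leaf = name.rsplit(".", 1)[-1]
        if name in ("tok_emb", "pos_emb"):
            params[name] = rng.normal(0.0, config.init_std, size=shape)
        elif leaf.startswith("w"):
            fan_in = shape[0]
            params[name] = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
        elif leaf.startswith("b"):
            params[name] = np.zeros(shape)
        elif leaf == "g":
            params[name] = np.ones(shape)
        else:  # pragma: no cover
            raise AssertionError(name)
    return LanguageModel(config, params)


def count_parameters(model: LanguageModel) -> int:
    """Total trainable entries (the tied output projection is not re-counted)."""
    return sum(v.size for v in model.params.values())


def forward_logprobs(model: LanguageModel, ids) -> np.ndarray:
    """(L, V) matrix of normalized next-token log-probabilities for one sequence."""
    ids = np.asarray(ids, dtype=int)
    if ids.ndim != 1:
        raise ValueError("forward_logprobs takes a single id sequence")
    logits = model.forward(ids[None, :])[0]
    m = logits.max(axis=-1, keepdims=True)
    return logits - (np.log(np.exp(logits - m).sum(axis=-1, keepdims=True)) + m)


@dataclass(frozen=True)
class NLLResult:
    total: float
    per_token: float
    n_terms: int

    @property
    def perplexity(self) -> float:
        return math.exp(self.per_token)


def sequence_nll(model: LanguageModel, ids) -> NLLResult:
    """Negative log-likelihood of tokens 2..L given their prefixes (nats)."""
    ids = np.asarray(ids, dtype=int)
    if ids.ndim != 1 or len(ids) < 2:
        raise ValueError("sequence_nll needs a single sequence of length >= 2")
    lp = forward_logprobs(model, ids)
    terms = lp[np.arange(len(ids) - 1), ids[1:]]
    total = float(-terms.sum())
    return NLLResult(total=total, per_token=total / (len(ids) - 1), n_terms=len(ids) - 1)
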