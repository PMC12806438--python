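"""The Delayformer network.

Each channel's input window is delay-embedded into an ``L x C`` Hankel image
(``C = W - L + 1``), sliced into ``p2 x p1`` patches, linearly projected to
``D`` dimensions and summed with a sinusoidal positional encoding.  A stack
of ``n_layers`` *post-norm* transformer encoder blocks,

    U   = LayerNorm(H + MSA(H))
    H'  = LayerNorm(U + FF(U)),

is applied with **identical weights to every channel** (channel independence:
one shared encoder cross-learns the dynamics from all variables).  The final
token matrix ``Z_k`` for channel ``k`` is flattened and mapped to the
``H``-step forecast of that channel by an affine head — one head per channel
by default (``decoder_mode="independent"``), or a single head shared by all
channels (``"shared"``, the configuration used for cross-dataset pretraining,
where a new dataset arrives with no channel-specific parameters).

Everything runs on NumPy; gradients are computed by the hand-derived
backward passes in :mod:`delayformer.nn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .embedding import PatchSpec, hankelize_batch, patchify_batch

__all__ = ["ModelConfig", "Delayformer", "sinusoidal_positions"]


@dataclass
class ModelConfig:
    """Architecture and geometry of one Delayformer.

    ``L`` is the delay-embedding dimension, ``(p1, p2)`` the patch shape
    (columns x rows) over the ``L x (W - L + 1)`` Hankel image, ``D`` the
    token width, and ``decoder_mode`` selects per-channel or shared forecast
    heads.
    """

    W: int = 96
    H: int = 96
    N: int = 30
    L: int = 49
    p1: int = 6
    p2: int = 7
    D: int = 128
    n_layers: int = 3
    n_heads: int = 8
    ff_dim: int = 256
    dropout: float = 0.1
    decoder_mode: str = "independent"  # or "shared"
    norm_style: str = "post"  # or "pre"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.D % self.n_heads != 0:
            raise ValueError(f"D={self.D} not divisible by n_heads={self.n_heads}")
        if self.D % 2 != 0:
            raise ValueError("D must be even for the sinusoidal encoding")
        if self.decoder_mode not in ("independent", "shared"):
            raise ValueError(f"unknown decoder_mode {self.decoder_mode!r}")
        if self.norm_style not in ("post", "pre"):
            raise ValueError(f"unknown norm_style {self.norm_style!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        # eagerly verify the embedding geometry
        self.patch_spec.validate(self.L, self.C)

    @property
    def C(self) -> int:
        return self.W - self.L + 1

    @property
    def patch_spec(self) -> PatchSpec:
        return PatchSpec(self.p1, self.p2)

    @property
    def n_tokens(self) -> int:
        return (self.L * self.C) // (self.p1 * self.p2)

    @property
    def token_dim(self) -> int:
        return self.p1 * self.p2

    @property
    def flat_dim(self) -> int:
        return self.n_tokens * self.D

    def np_dtype(self):
        return np.dtype(self.dtype)


def sinusoidal_positions(n_tokens: int, D: int) -> np.ndarray:
    """Parameter-free sinusoidal positional encoding.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/D))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/D))``.
    """
    if D % 2 != 0:
        raise ValueError("D must be even")
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(D // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / D)
    pe = np.empty((n_tokens, D))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class Delayformer:
    """Shared-encoder, per-channel-head forecaster over Hankel patch tokens."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.init_seed = int(seed)
        cfg = config
        dt = cfg.np_dtype()
        rng = np.random.default_rng(seed)
        P: dict[str, np.ndarray] = {}
        P["embed.W"] = _xavier(rng, cfg.token_dim, cfg.D, (cfg.token_dim, cfg.D), dt)
        P["embed.b"] = np.zeros(cfg.D, dtype=dt)
        for l in range(cfg.n_layers):
            p = f"block{l}."
            P[p + "Wqkv"] = _xavier(rng, cfg.D, cfg.D, (cfg.D, 3 * cfg.D), dt)
            P[p + "bqkv"] = np.zeros(3 * cfg.D, dtype=dt)
            P[p + "Wo"] = _xavier(rng, cfg.D, cfg.D, (cfg.D, cfg.D), dt)
            P[p + "bo"] = np.zeros(cfg.D, dtype=dt)
            P[p + "ln1.g"] = np.ones(cfg.D, dtype=dt)
            P[p + "ln1.b"] = np.zeros(cfg.D, dtype=dt)
            P[p + "W1"] = _xavier(rng, cfg.D, cfg.ff_dim, (cfg.D, cfg.ff_dim), dt)
            P[p + "b1"] = np.zeros(cfg.ff_dim, dtype=dt)
            P[p + "W2"] = _xavier(rng, cfg.ff_dim, cfg.D, (cfg.ff_dim, cfg.D), dt)
            P[p + "b2"] = np.zeros(cfg.D, dtype=dt)
            P[p + "ln2.g"] = np.ones(cfg.D, dtype=dt)
            P[p + "ln2.b"] = np.zeros(cfg.D, dtype=dt)
        F = cfg.flat_dim
        if cfg.decoder_mode == "independent":
            P["head.W"] = np.stack(
                [_xavier(rng, F, cfg.H, (F, cfg.H), dt) for _ in range(cfg.N)]
            )
            P["head.b"] = np.zeros((cfg.N, cfg.H), dtype=dt)
        else:
            P["head.W"] = _xavier(rng, F, cfg.H, (F, cfg.H), dt)
            P["head.b"] = np.zeros(cfg.H, dtype=dt)
        self.params = P
        self.pe = sinusoidal_positions(cfg.n_tokens, cfg.D).astype(dt)

    # ------------------------------------------------------------------ ops

    def tokenize(self, batch: np.ndarray) -> np.ndarray:
        """``(B, W, N)`` windows -> ``(B*N, n_tokens, p1*p2)`` patch tokens.

        Channels are peeled off, each window delay-embedded into its Hankel
        image (intermediate shape ``(B, N, L, C)``) and sliced into patches.
        """
        cfg = self.config
        batch = np.asarray(batch)
        if batch.ndim != 3:
            raise ValueError(f"expected a (B, W, N) batch, got shape {batch.shape}")
        B, W, N = batch.shape
        if W != cfg.W:
            raise ValueError(f"window axis: got W={W}, config expects {cfg.W}")
        # Per-channel heads are bound to a fixed channel count; the shared
        # head (used in foundation mode) is channel-count agnostic.
        if cfg.decoder_mode == "independent" and N != cfg.N:
            raise ValueError(f"channel axis: got N={N}, config expects {cfg.N}")
        chans = batch.transpose(0, 2, 1).reshape(B * N, W)
        images = hankelize_batch(chans, cfg.L)  # (B*N, L, C)
        tokens = patchify_batch(images, cfg.patch_spec)
        return tokens.astype(cfg.np_dtype())

    def embed_patches(self, tokens: np.ndarray) -> np.ndarray:
        """Project flat patches to ``D`` dims and add the positional encoding (state ``H^0``)."""
        if tokens.shape[-1] != self.config.token_dim:
            raise ValueError(
                f"token length {tokens.shape[-1]} != p1*p2 = {self.config.token_dim}"
            )
        h0, _ = nn.linear_forward(tokens, self.params["embed.W"], self.params["embed.b"])
        return h0 + self.pe

    def encoder_block(self, state: np.ndarray, layer: int, rng=None) -> np.ndarray:
        """Apply encoder block ``layer`` (post-norm residual composition)."""
        out, _ = self._block_forward(state, layer, rng)
        return out

    def encode(self, h0: np.ndarray, rng=None) -> np.ndarray:
        """Run all encoder blocks; the result is the representation ``Z``."""
        h = h0
        for l in range(self.config.n_layers):
            h = self.encoder_block(h, l, rng)
        return h

    def decode_channel(self, Z_k: np.ndarray, k: int) -> np.ndarray:
        """Map one channel's ``n_tokens x D`` representation to its length-H forecast."""
        cfg = self.config
        if not 0 <= k < cfg.N:
            raise IndexError(f"channel index {k} out of range [0, {cfg.N})")
        flat = np.asarray(Z_k).reshape(cfg.flat_dim)
        if cfg.decoder_mode == "independent":
            return flat @ self.params["head.W"][k] + self.params["head.b"][k]
        return flat @ self.params["head.W"] + self.params["head.b"]

    # ------------------------------------------------------- forward/backward

    def _block_forward(self, h, layer, rng):
        P = self.params
        cfg = self.config
        p = f"block{layer}."
        if cfg.norm_style == "post":
            a, c_msa = nn.mhsa_forward(
                h, P[p + "Wqkv"], P[p + "bqkv"], P[p + "Wo"], P[p + "bo"], cfg.n_heads
            )
            a_d, m_a = nn.dropout_forward(a, cfg.dropout, rng)
            u, c_ln1 = nn.layernorm_forward(h + a_d, P[p + "ln1.g"], P[p + "ln1.b"])
            f1, c_l1 = nn.linear_forward(u, P[p + "W1"], P[p + "b1"])
            f1r, m_relu = nn.relu_forward(f1)
            f2, c_l2 = nn.linear_forward(f1r, P[p + "W2"], P[p + "b2"])
            f_d, m_f = nn.dropout_forward(f2, cfg.dropout, rng)
            out, c_ln2 = nn.layernorm_forward(u + f_d, P[p + "ln2.g"], P[p + "ln2.b"])
        else:  # pre-norm escape hatch
            hn, c_ln1 = nn.layernorm_forward(h, P[p + "ln1.g"], P[p + "ln1.b"])
            a, c_msa = nn.mhsa_forward(
                hn, P[p + "Wqkv"], P[p + "bqkv"], P[p + "Wo"], P[p + "bo"], cfg.n_heads
            )
            a_d, m_a = nn.dropout_forward(a, cfg.dropout, rng)
            u = h + a_d
            un, c_ln2 = nn.layernorm_forward(u, P[p + "ln2.g"], P[p + "ln2.b"])
            f1, c_l1 = nn.linear_forward(un, P[p + "W1"], P[p + "b1"])
            f1r, m_relu = nn.relu_forward(f1)
            f2, c_l2 = nn.linear_forward(f1r, P[p + "W2"], P[p + "b2"])
            f_d, m_f = nn.dropout_forward(f2, cfg.dropout, rng)
            out = u + f_d
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(f"non-finite activations in encoder block {layer}")
        return out, (c_msa, m_a, c_ln1, c_l1, m_relu, c_l2, m_f, c_ln2)

    def _block_backward(self, dout, layer, cache, grads):
        P = self.params
        cfg = self.config
        p = f"block{layer}."
        c_msa, m_a, c_ln1, c_l1, m_relu, c_l2, m_f, c_ln2 = cache
        if cfg.norm_style == "post":
            dr2, dg2, db2 = nn.layernorm_backward(dout, c_ln2)
            grads[p + "ln2.g"] += dg2
            grads[p + "ln2.b"] += db2
            df2 = nn.dropout_backward(dr2, m_f)
            df1r, dW2, db_2 = nn.linear_backward(df2, c_l2)
            grads[p + "W2"] += dW2
            grads[p + "b2"] += db_2
            df1 = nn.relu_backward(df1r, m_relu)
            du_ff, dW1, db_1 = nn.linear_backward(df1, c_l1)
            grads[p + "W1"] += dW1
            grads[p + "b1"] += db_1
            du = dr2 + du_ff
            dr1, dg1, db1 = nn.layernorm_backward(du, c_ln1)
            grads[p + "ln1.g"] += dg1
            grads[p + "ln1.b"] += db1
            da = nn.dropout_backward(dr1, m_a)
            dh_msa, dWqkv, dbqkv, dWo, dbo = nn.mhsa_backward(da, c_msa)
            grads[p + "Wqkv"] += dWqkv
            grads[p + "bqkv"] += dbqkv
            grads[p + "Wo"] += dWo
            grads[p + "bo"] += dbo
            return dr1 + dh_msa
        # pre-norm
        df2 = nn.dropout_backward(dout, m_f)
        df1r, dW2, db_2 = nn.linear_backward(df2, c_l2)
        grads[p + "W2"] += dW2
        grads[p + "b2"] += db_2
        df1 = nn.relu_backward(df1r, m_relu)
        dun, dW1, db_1 = nn.linear_backward(df1, c_l1)
        grads[p + "W1"] += dW1
        grads[p + "b1"] += db_1
        du, dg2, db2 = nn.layernorm_backward(dun, c_ln2)
        grads[p + "ln2.g"] += dg2
        grads[p + "ln2.b"] += db2
        du = du + dout
        da = nn.dropout_backward(du, m_a)
        dhn, dWqkv, dbqkv, dWo, dbo = nn.mhsa_backward(da, c_msa)
        grads[p + "Wqkv"] += dWqkv
        grads[p + "bqkv"] += dbqkv
        grads[p + "Wo"] += dWo
        grads[p + "bo"] += dbo
        dh, dg1, db1 = nn.layernorm_backward(dhn, c_ln1)
        grads[p + "ln1.g"] += dg1
        grads[p + "ln1.b"] += db1
        return dh + du

    def forward(self, batch: np.ndarray, rng=None) -> np.ndarray:
        """``(B, W, N)`` -> ``(B, H, N)`` forecasts (evaluation mode unless ``rng`` given)."""
        out, _ = self.forward_cached(batch, rng)
        return out

    def forward_cached(self, batch: np.ndarray, rng=None):
        cfg = self.config
        batch = np.asarray(batch)
        B, _, N = batch.shape
        tokens = self.tokenize(batch)  # (B*N, T, P)
        h, c_embed = nn.linear_forward(tokens, self.params["embed.W"], self.params["embed.b"])
        h = h + self.pe
        h, m_pe = nn.dropout_forward(h, cfg.dropout, rng)
        block_caches = []
        for l in range(cfg.n_layers):
            h, cache = self._block_forward(h, l, rng)
            block_caches.append(cache)
        Z = h.reshape(B, N, cfg.flat_dim)
        if cfg.decoder_mode == "independent":
            # batched per-channel heads: (N, B, F) @ (N, F, H) -> (N, B, H)
            y = np.ascontiguousarray(Z.transpose(1, 0, 2)) @ self.params["head.W"]
            y = y.transpose(1, 0, 2) + self.params["head.b"]
        else:
            y = Z @ self.params["head.W"] + self.params["head.b"]
        out = y.transpose(0, 2, 1)  # (B, H, N)
        return out, (c_embed, m_pe, block_caches, Z)

    def backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss w.r.t. every parameter, given d(loss)/d(forecast)."""
        cfg = self.config
        c_embed, m_pe, block_caches, Z = cache
        B, _, N = dout.shape
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dy = np.ascontiguousarray(dout.transpose(0, 2, 1)).astype(Z.dtype)  # (B, N, H)
        if cfg.decoder_mode == "independent":
            Zt = np.ascontiguousarray(Z.transpose(1, 0, 2))  # (N, B, F)
            dyt = np.ascontiguousarray(dy.transpose(1, 0, 2))  # (N, B, H)
            grads["head.W"] += Zt.transpose(0, 2, 1) @ dyt  # (N, F, H)
            grads["head.b"] += dy.sum(axis=0)
            dZ = (dyt @ self.params["head.W"].transpose(0, 2, 1)).transpose(1, 0, 2)
        else:
            Z2 = Z.reshape(-1, cfg.flat_dim)
            dy2 = dy.reshape(-1, cfg.H)
            grads["head.W"] += Z2.T @ dy2
            grads["head.b"] += dy2.sum(axis=0)
            dZ = dy @ self.params["head.W"].T
        dh = dZ.reshape(B * N, cfg.n_tokens, cfg.D)
        for l in range(cfg.n_layers - 1, -1, -1):
            dh = self._block_backward(dh, l, block_caches[l], grads)
        dh = nn.dropout_backward(dh, m_pe)
        _, dWe, dbe = nn.linear_backward(dh, c_embed)
        grads["embed.W"] += dWe
        grads["embed.b"] += dbe
        return grads

    # ------------------------------------------------------------ persistence

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a self-describing JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {"config": asdict(self.config), "init_seed": self.init_seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Delayformer":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**sidecar["config"]), seed=sidecar.get("init_seed", 0))
        with np.load(path.with_suffix(".npz")) as data:
            for k in model.params:
                model.params[k] = data[k]
        return model

    def copy(self) -> "Delayformer":
        clone = Delayformer(self.config, seed=self.init_seed)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone
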