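"""Delay embedding: sliding windows, Hankel images, and patch tokenization.

One channel's input window ``w = (w_0, ..., w_{W-1})`` is delay-embedded into
an ``L x C`` Hankel matrix with ``C = W - L + 1`` columns,

    Y[i, j] = w[i + j],

whose column ``j`` is the L-lag delay vector starting at time ``j``.  Every
anti-diagonal of ``Y`` is constant, so the matrix is a redundant 2-D "image"
of the window; under the delay-embedding theorems its columns trace out a
reconstruction of the underlying system state.  The image is sliced into
non-overlapping ``p2 x p1`` tiles (``p2`` rows = lags, ``p1`` columns = time
offsets) that become flat tokens for a patch-transformer encoder.

``dehankelize`` / ``unpatchify`` are the exact inverses used for testing and
for turning Hankel-shaped outputs back into series; ``dehankelize`` averages
along anti-diagonals, so it is also well-defined for matrices that violate
the Hankel constraint only approximately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import MultivariateSeries

__all__ = [
    "WindowPair",
    "HankelImage",
    "PatchSpec",
    "make_windows",
    "hankelize",
    "dehankelize",
    "patchify",
    "unpatchify",
    "hankelize_batch",
    "patchify_batch",
]


@dataclass
class WindowPair:
    """One supervised example: a ``W x N`` input window and its ``H x N`` target."""

    input: np.ndarray
    target: np.ndarray
    start_index: int

    def __post_init__(self) -> None:
        if self.input.ndim != 2 or self.target.ndim != 2:
            raise ValueError("input and target must be 2-D (time x channels)")
        if self.input.shape[1] != self.target.shape[1]:
            raise ValueError("input and target must share the channel axis")


@dataclass
class HankelImage:
    """The ``L x C`` delay-embedding matrix of one channel's window."""

    matrix: np.ndarray
    channel: int = 0

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def C(self) -> int:
        return self.matrix.shape[1]

    @property
    def window_length(self) -> int:
        return self.L + self.C - 1

    def is_hankel(self, atol: float = 0.0) -> bool:
        """True when every anti-diagonal is constant (within ``atol``)."""
        m = self.matrix
        if m.shape[0] < 2 or m.shape[1] < 2:
            return True
        return bool(np.allclose(m[1:, :-1], m[:-1, 1:], rtol=0.0, atol=atol))


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: ``p1`` columns x ``p2`` rows per tile."""

    p1: int
    p2: int

    def __post_init__(self) -> None:
        if self.p1 < 1 or self.p2 < 1:
            raise ValueError("patch sides must be >= 1")

    @property
    def token_dim(self) -> int:
        return self.p1 * self.p2

    def validate(self, L: int, C: int) -> None:
        """Check the divisibility constraints for an ``L x C`` image."""
        bad = []
        if C % self.p1 != 0:
            bad.append(f"p1={self.p1} does not divide C={C}")
        if L % self.p2 != 0:
            bad.append(f"p2={self.p2} does not divide L={L}")
        if bad:
            raise ValueError("; ".join(bad))

    def n_tokens(self, L: int, C: int) -> int:
        self.validate(L, C)
        return (L * C) // self.token_dim


def make_windows(
    series: MultivariateSeries, W: int, H: int, stride: int = 1
) -> list[WindowPair]:
    """Sliding ``(input, target)`` pairs starting at 0, stride, 2*stride, ...

    The count is ``floor((T - W - H) / stride) + 1``.
    """
    if W < 1 or H < 0:
        raise ValueError("need W >= 1 and H >= 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    T = series.n_samples
    if W + H > T:
        raise ValueError(f"series length {T} < minimum W + H = {W + H}")
    pairs = []
    for s in range(0, T - W - H + 1, stride):
        pairs.append(
            WindowPair(
                input=series.values[s : s + W],
                target=series.values[s + W : s + W + H],
                start_index=s,
            )
        )
    return pairs


def hankelize(channel_window: np.ndarray, L: int, channel: int = 0) -> HankelImage:
    """Delay-embed a length-``W`` vector into the ``L x (W - L + 1)`` Hankel matrix."""
    w = np.asarray(channel_window, dtype=np.float64).reshape(-1)
    W = w.size
    if not 1 <= L <= W:
        raise ValueError(f"embedding dimension L={L} out of range [1, {W}]")
    C = W - L + 1
    i = np.arange(L)[:, None]
    j = np.arange(C)[None, :]
    return HankelImage(matrix=w[i + j], channel=channel)


def dehankelize(image: HankelImage | np.ndarray) -> np.ndarray:
    """Invert :func:`hankelize` by averaging along anti-diagonals.

    Exact inverse when the Hankel constraint holds; otherwise each output
    entry ``t`` is the mean of ``matrix[i, j]`` over ``i + j == t``.
    """
    m = image.matrix if isinstance(image, HankelImage) else np.asarray(image, dtype=np.float64)
    L, C = m.shape
    W = L + C - 1
    sums = np.zeros(W)
    counts = np.zeros(W)
    idx = (np.arange(L)[:, None] + np.arange(C)[None, :]).ravel()
    np.add.at(sums, idx, m.ravel())
    np.add.at(counts, idx, 1.0)
    return sums / counts


def patchify(image: HankelImage, spec: PatchSpec) -> np.ndarray:
    """Slice an image into ``(L*C)/(p1*p2)`` flat tokens of length ``p1*p2``.

    Tiles are taken row-major over the tile grid and flattened row-major
    within each tile; the value multiset is conserved.
    """
    m = image.matrix if isinstance(image, HankelImage) else np.asarray(image)
    L, C = m.shape
    spec.validate(L, C)
    tiles = m.reshape(L // spec.p2, spec.p2, C // spec.p1, spec.p1)
    tokens = tiles.transpose(0, 2, 1, 3).reshape(-1, spec.token_dim)
    return tokens


def unpatchify(tokens: np.ndarray, spec: PatchSpec, L: int, C: int) -> np.ndarray:
    """Exact left inverse of :func:`patchify`: reassemble the ``L x C`` matrix."""
    tokens = np.asarray(tokens)
    spec.validate(L, C)
    n_tok = (L * C) // spec.token_dim
    if tokens.shape != (n_tok, spec.token_dim):
        raise ValueError(
            f"expected {n_tok} tokens of length {spec.token_dim}, got array of shape {tokens.shape}"
        )
    tiles = tokens.reshape(L // spec.p2, C // spec.p1, spec.p2, spec.p1)
    return tiles.transpose(0, 2, 1, 3).reshape(L, C)


# --- batched forms used by the model's forward pass ------------------------


def hankelize_batch(windows: np.ndarray, L: int) -> np.ndarray:
    """Vectorized hankelize: ``(..., W)`` -> ``(..., L, W - L + 1)``."""
    windows = np.asarray(windows)
    W = windows.shape[-1]
    if not 1 <= L <= W:
        raise ValueError(f"embedding dimension L={L} out of range [1, {W}]")
    C = W - L + 1
    idx = np.arange(L)[:, None] + np.arange(C)[None, :]
    return windows[..., idx]


def patchify_batch(images: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Vectorized patchify: ``(..., L, C)`` -> ``(..., n_tokens, p1*p2)``."""
    images = np.asarray(images)
    L, C = images.shape[-2:]
    spec.validate(L, C)
    lead = images.shape[:-2]
    tiles = images.reshape(*lead, L // spec.p2, spec.p2, C // spec.p1, spec.p1)
    order = tuple(range(len(lead))) + tuple(
        len(lead) + ax for ax in (0, 2, 1, 3)
    )
    return tiles.transpose(order).reshape(*lead, -1, spec.token_dim)
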