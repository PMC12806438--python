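"""Multivariate time-series container shared by every stage of the pipeline.

A :class:`MultivariateSeries` is a plain ``T x N`` float matrix (rows = time,
columns = channels) plus channel names, the sampling interval, and a free-text
provenance string recording how the series was produced (simulator config,
file path, seed ...).  It deliberately carries no missing-value machinery:
the forecaster assumes complete, regularly sampled observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["MultivariateSeries"]


@dataclass
class MultivariateSeries:
    """A ``T x N`` block of regularly sampled observations.

    Parameters
    ----------
    values
        Array of shape ``(T, N)``; time runs down the rows.
    channel_names
        ``N`` labels, one per column.
    dt_sample
        Time between consecutive rows (arbitrary units; metadata only).
    provenance
        Free text describing origin (config + seed, or source file).
    """

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    dt_sample: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (T x N), got shape {self.values.shape}")
        # T == 0 is tolerated so chronological splits may have an empty part.
        if self.values.shape[1] < 1:
            raise ValueError(f"series needs N >= 1 channels, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite entries")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[1])]
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.values.shape[1]} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select_channels(self, channels: Sequence[str] | Sequence[int]) -> "MultivariateSeries":
        """Return a new series restricted to the given channels (names or indices), in the given order."""
        if len(channels) == 0:
            raise ValueError("channel selection resolved to zero channels")
        idx: list[int] = []
        for c in channels:
            if isinstance(c, str):
                try:
                    idx.append(self.channel_names.index(c))
                except ValueError:
                    raise KeyError(f"unknown channel {c!r}") from None
            else:
                if not 0 <= int(c) < self.n_channels:
                    raise IndexError(f"channel index {c} out of range [0, {self.n_channels})")
                idx.append(int(c))
        return replace(
            self,
            values=self.values[:, idx].copy(),
            channel_names=[self.channel_names[i] for i in idx],
        )

    def slice_time(self, start: int, stop: int) -> "MultivariateSeries":
        """Contiguous time slice ``[start, stop)`` as a new series."""
        if not 0 <= start <= stop <= self.n_samples:
            raise ValueError(f"bad time slice [{start}, {stop}) for T={self.n_samples}")
        return replace(self, values=self.values[start:stop].copy())
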