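"""Variance-based channel selection.

Seizure activity raises signal amplitude — hence variance — on the scalp
channels nearest the focus, so ranking channels of an epoch by amplitude
variance and keeping the few largest is a cheap, reference-free way to drop
uninformative channels before feature extraction. The default keeps the top
3 of 23.

The ranking variance uses the population normalization ``(1/K) Σ (x − μ)²``;
the choice of normalization cannot change the ranking, but it is kept
explicit so the printed per-channel values are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import Window

logger = logging.getLogger(__name__)

__all__ = ["ChannelRanking", "channel_variance", "select_top_k"]


@dataclass
class ChannelRanking:
    """Per-channel variances and the ordered indices of the selected top k."""

    variances: np.ndarray
    selected: np.ndarray  # channel indices, descending variance
    k: int

    def to_frame(self, channel_labels=None) -> pd.DataFrame:
        n = len(self.variances)
        labels = channel_labels if channel_labels is not None else [
            f"CH{i + 1}" for i in range(n)
        ]
        return pd.DataFrame(
            {
                "channel": labels,
                "variance": self.variances,
                "selected": np.isin(np.arange(n), self.selected),
            }
        )

    def to_csv(self, path, channel_labels=None) -> None:
        self.to_frame(channel_labels).to_csv(path, index=False)


def channel_variance(window: Window | np.ndarray) -> np.ndarray:
    """Population variance of each channel's amplitude over the epoch."""
    signal = window.signal if isinstance(window, Window) else np.asarray(window, float)
    if signal.ndim != 2 or signal.shape[1] < 1:
        raise ValueError("window must carry >= 1 sample per channel")
    return np.var(signal, axis=1, ddof=0)


def select_top_k(variances, k: int = 3) -> ChannelRanking:
    """Indices of the ``k`` largest variances, descending; ties by lower index.

    Asking for more channels than exist returns them all with a logged
    warning rather than an error.
    """
    variances = np.asarray(variances, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(variances)
    if k > n:
        logger.warning("k=%d exceeds %d channels; selecting all", k, n)
        k = n
    order = np.argsort(-variances, kind="stable")  # stable: ties keep lower index
    return ChannelRanking(variances=variances, selected=order[:k], k=k)
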