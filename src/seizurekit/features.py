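"""Statistical feature extraction from EEG epochs.

Eleven features are computed from each selected channel of a 10-s epoch and
then averaged element-wise across the selected channels, giving one 11-value
row per epoch. The eleven features, in the canonical column order used
throughout this package:

========  =============================================================
STD       sample standard deviation, 1/(N−1) normalization (µV)
Mean      arithmetic mean (µV)
Max       largest sample value (µV)
Min       smallest sample value (µV)
Var       STD², i.e. the 1/(N−1) sample variance (µV²)
Med       sample median (µV)
SKW       skewness: third standardized population moment (dimensionless)
ENT       Shannon entropy (natural log) of the normalized amplitude
          histogram, 100 bins by default (nats)
KRT       kurtosis: fourth standardized population moment, non-excess
          (Gaussian → 3; dimensionless)
MOM       central population moment of order 4 by default (µV⁴)
POW       spectral power: Σ F·conj(F) over the unnormalized DFT of the
          epoch, which equals N·Σx² by Parseval's theorem (µV²·samples²)
========  =============================================================

Two exact identities tie the conventions down and serve as self-checks:
``POW = N·Σx²`` and ``MOM = KRT·σ_pop⁴`` (population σ, moment order 4).
On a zero-variance signal SKW and KRT are undefined and are returned as 0
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import stats

from .channels import select_top_k, channel_variance
from .records import SEIZURE, Window

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "STATE_COLUMN",
    "STATE_SEIZURE",
    "STATE_NORMAL",
    "FeatureVector",
    "extract_features",
    "average_features",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_COLUMNS = [
    "STD", "Mean", "Max", "Min", "Var", "Med", "SKW", "ENT", "KRT", "MOM", "POW",
]
STATE_COLUMN = "State"
STATE_SEIZURE = "s"
STATE_NORMAL = "n"

# dataclass field name -> table column name
_FIELD_TO_COLUMN = {
    "std": "STD", "mean": "Mean", "max": "Max", "min": "Min", "var": "Var",
    "med": "Med", "skw": "SKW", "ent": "ENT", "krt": "KRT", "mom": "MOM",
    "pow": "POW",
}


@dataclass(frozen=True)
class FeatureVector:
    """The eleven features of one channel (or a channel-average)."""

    std: float
    mean: float
    max: float
    min: float
    var: float
    med: float
    skw: float
    ent: float
    krt: float
    mom: float
    pow: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {col: getattr(self, f) for f, col in _FIELD_TO_COLUMN.items()}
        )


def extract_features(
    channel_signal,
    moment_order: int = 4,
    entropy_bins: int = 100,
    entropy_base: float | None = None,
) -> FeatureVector:
    """Compute the eleven features of a single-channel signal.

    Parameters
    ----------
    channel_signal : array-like of float
        Amplitude samples of one channel, at least 4 of them (the
        fourth-moment features need that many).
    moment_order : int
        Order of the central moment reported as MOM (default 4).
    entropy_bins : int
        Histogram bins for the entropy estimate (default 100).
    entropy_base : float, optional
        Logarithm base for entropy; natural log when omitted.
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 samples to extract features, got {n}")
    mu = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    m2 = float(np.mean((x - mu) ** 2))  # population second moment
    # spread at or below float rounding of the signal's own magnitude is
    # indistinguishable from a constant signal
    degenerate = m2 <= 1e-24 * max(float(np.mean(x**2)), 1e-300)
    if degenerate:
        logger.warning("zero-variance signal: skewness/kurtosis undefined, set to 0")
        skw = krt = 0.0
    else:
        skw = float(np.mean((x - mu) ** 3) / m2**1.5)
        krt = float(np.mean((x - mu) ** 4) / m2**2)
    counts, _ = np.histogram(x, bins=entropy_bins)
    ent = float(stats.entropy(counts / n, base=entropy_base))
    f = np.fft.fft(x)
    power = float(np.sum(f * np.conj(f)).real)
    return FeatureVector(
        std=std,
        mean=mu,
        max=float(np.max(x)),
        min=float(np.min(x)),
        var=std**2,
        med=float(np.median(x)),
        skw=skw,
        ent=ent,
        krt=krt,
        mom=float(np.mean((x - mu) ** moment_order)),
        pow=power,
    )


def average_features(vectors: list[FeatureVector]) -> FeatureVector:
    """Element-wise arithmetic mean of feature vectors (one per channel)."""
    if len(vectors) == 0:
        raise ValueError("cannot average an empty sequence of feature vectors")
    names = [f.name for f in dc_fields(FeatureVector)]
    return FeatureVector(
        **{
            name: float(np.mean([getattr(v, name) for v in vectors]))
            for name in names
        }
    )


def build_feature_table(
    windows: list[Window],
    k: int = 3,
    moment_order: int = 4,
    entropy_bins: int = 100,
    entropy_base: float | None = None,
) -> pd.DataFrame:
    """One averaged 11-feature row per epoch, with its label.

    For each epoch: rank channels by amplitude variance, extract the eleven
    features from each of the top-``k`` channels, average them element-wise,
    and attach the epoch's label (``State`` column, ``"s"``/``"n"``) plus
    ``record_id`` and ``start_s`` metadata.
    """
    if len(windows) == 0:
        raise ValueError("windows must be non-empty")
    rows = []
    for win in windows:
        ranking = select_top_k(channel_variance(win), k)
        vecs = [
            extract_features(
                win.signal[c],
                moment_order=moment_order,
                entropy_bins=entropy_bins,
                entropy_base=entropy_base,
            )
            for c in ranking.selected
        ]
        row = average_features(vecs).to_series()
        row[STATE_COLUMN] = STATE_SEIZURE if win.label == SEIZURE else STATE_NORMAL
        row["record_id"] = win.record_id
        row["start_s"] = win.start_s
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV in the canonical column order."""
    cols = FEATURE_COLUMNS + [STATE_COLUMN]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV, checking the eleven feature columns exist."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS + [STATE_COLUMN] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table is missing columns {missing}")
    return df
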