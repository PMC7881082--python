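"""Synthetic scalp-EEG records and feature tables.

The generator emulates the statistical structure the detection pipeline
relies on — not scalp physiology. A record carries ``n_channels`` (23 by
default, as in public pediatric scalp EEG databases) of band-limited
(1–30 Hz) 1/f-weighted colored noise at ``fs`` = 256 Hz with per-channel
standard deviation ``background_sd`` (50 µV). Within each annotated seizure
interval, a subset of channels (``burst_channels``) additionally carries a
rhythmic spike-wave component at ``spike_freq_hz`` (3 Hz) whose RMS
amplitude is ``amplitude_factor × background_sd``, so the expected ictal
variance on burst channels is ``(1 + amplitude_factor²)`` times the
interictal variance — the higher-amplitude ictal signature that variance
ranking presumes. Everything is driven by one seed.

:func:`simulate_feature_table` bypasses the signal stage and draws averaged
11-feature rows directly from two log-scale distributions whose per-feature
separations follow the direction seen in real averaged tables (seizure rows
carry larger STD/Var/POW/MOM and more extreme Max/Min, and *lower* kurtosis
— high-amplitude rhythmic activity is platykurtic relative to background).
``effect`` scales the per-feature class separation in within-class SD
units; ``effect = 0`` makes the two classes identically distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, STATE_COLUMN, STATE_NORMAL, STATE_SEIZURE
from .records import EEGRecord, SeizureAnnotation

__all__ = ["SynthConfig", "simulate_record", "simulate_feature_table"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator."""

    duration_s: float
    n_channels: int = 23
    fs: float = 256.0
    seizure_intervals: tuple = ()
    burst_channels: tuple = (1, 5, 20)  # 0-based; CH2/CH6/CH21 of a 23-ch montage
    amplitude_factor: float = 3.0
    background_sd: float = 50.0
    spike_freq_hz: float = 3.0
    seed: int = 0
    record_id: str = field(default="")

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0 or self.n_channels < 1:
            raise ValueError("duration_s, fs and n_channels must be positive")
        if self.amplitude_factor < 1:
            raise ValueError("amplitude_factor must be >= 1")
        ivals = sorted((float(a), float(b)) for a, b in self.seizure_intervals)
        for a, b in ivals:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(f"seizure interval [{a}, {b}) out of range")
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError("seizure intervals must be disjoint")
        self.seizure_intervals = tuple(ivals)
        if any(not 0 <= c < self.n_channels for c in self.burst_channels):
            raise ValueError("burst_channels must be valid channel indices")
        if not self.record_id:
            self.record_id = f"synth-{self.seed}"

    def to_dict(self) -> dict:
        return asdict(self)


def _colored_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Band-limited (1–30 Hz) 1/f-weighted noise with the requested SD."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.zeros_like(freqs)
    band = (freqs >= 1.0) & (freqs <= 30.0)
    weight[band] = 1.0 / np.sqrt(freqs[band])
    x = np.fft.irfft(spectrum * weight, n)
    realized = x.std()
    return x * (sd / realized) if realized > 0 else x


def _spike_wave(
    rng: np.random.Generator, t: np.ndarray, freq: float, rms: float
) -> np.ndarray:
    """Rhythmic spike-wave: slow sinusoid plus a sharp spike each cycle."""
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * t + phase)
    # Gaussian spike (25 ms wide) once per cycle, placed by cycle phase
    cycle_pos = np.mod(freq * t + phase / (2 * np.pi), 1.0)
    spikes = np.exp(-0.5 * ((cycle_pos - 0.5) / (0.025 * freq)) ** 2)
    component = wave + 2.0 * (spikes - spikes.mean())
    return component * (rms / component.std())


def simulate_record(cfg: SynthConfig) -> EEGRecord:
    """Generate one annotated multichannel record under ``cfg``.

    Fully deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    signal = np.vstack(
        [_colored_noise(rng, n, cfg.fs, cfg.background_sd) for _ in range(cfg.n_channels)]
    )
    rms = cfg.amplitude_factor * cfg.background_sd
    for a, b in cfg.seizure_intervals:
        i0, i1 = int(round(a * cfg.fs)), min(int(round(b * cfg.fs)), n)
        t = np.arange(i0, i1) / cfg.fs
        for c in cfg.burst_channels:
            signal[c, i0:i1] += _spike_wave(rng, t, cfg.spike_freq_hz, rms)
    return EEGRecord(
        signal=signal,
        fs=cfg.fs,
        channel_labels=[f"CH{i + 1}" for i in range(cfg.n_channels)],
        annotations=[SeizureAnnotation(a, b) for a, b in cfg.seizure_intervals],
        record_id=cfg.record_id,
    )


# Per-feature generative recipe for the direct-to-feature shortcut. Scale
# features are drawn in log space around magnitudes typical of averaged
# 10-s scalp EEG epochs; "loading" is the coefficient on the shared severity
# latent, "noise" the independent per-feature log/linear noise SD.
_N_SAMPLES_PER_EPOCH = 2560  # 10 s at 256 Hz; fixes the POW = N^2(Var+Mean^2) scale


def simulate_feature_table(
    n_per_class: int, effect: float, seed: int = 0
) -> pd.DataFrame:
    """Draw averaged 11-feature rows for two classes directly.

    Rows follow the schema of :func:`seizurekit.features.build_feature_table`
    (eleven feature columns, ``State`` of ``"s"``/``"n"``, ``record_id``,
    ``start_s``). A shared per-row severity latent, mean ``±effect/2`` by
    class, drives the informative features so their pairwise correlations
    resemble a real table; derived features (Var, MOM, POW) are computed
    from the drawn ones so the package's internal identities approximately
    hold on synthetic rows too.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for state, sign in ((STATE_SEIZURE, +1.0), (STATE_NORMAL, -1.0)):
        for i in range(n_per_class):
            # severity latent per row: shared variance 0.25; each informative
            # feature adds independent variance 0.75, so per-feature
            # within-class SD is 1 and the class separation is `effect` SDs
            u = sign * effect / 2.0 + rng.normal(0.0, 0.5)
            latent = lambda: u + rng.normal(0.0, np.sqrt(0.75))
            sigma = 300.0 * np.exp(0.25 * latent())
            mean = rng.normal(0.0, 4.0)
            mx = sigma * np.exp(rng.normal(1.05, 0.12))
            mn = -sigma * np.exp(rng.normal(1.05, 0.12))
            med = rng.normal(0.0, 8.0)
            skw = rng.normal(0.0, 0.25)
            ent = 4.3 + 0.12 * latent()
            krt = np.exp(1.75 - 0.3 * latent())
            var = sigma**2
            mom = krt * var**2
            power = _N_SAMPLES_PER_EPOCH**2 * (var + mean**2)
            rows.append(
                dict(
                    zip(
                        FEATURE_COLUMNS,
                        [sigma, mean, mx, mn, var, med, skw, ent, krt, mom, power],
                    )
                )
                | {STATE_COLUMN: state, "record_id": f"synthtab-{seed}", "start_s": float(i)}
            )
    return pd.DataFrame(rows)
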