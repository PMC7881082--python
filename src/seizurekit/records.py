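"""In-memory EEG containers and epoch windowing.

An :class:`EEGRecord` is a channels-by-samples matrix in microvolts with a
sampling rate and a list of seizure annotation intervals (seconds, half-open
``[start_s, end_s)``). Classification operates on fixed-length multichannel
epochs (:class:`Window`), 10 s by default, labeled ``"seizure"`` when the
epoch lies entirely inside an annotated interval and ``"normal"`` when it
lies entirely outside all of them. Epochs that straddle an annotation
boundary are never emitted.

Two windowing protocols are provided:

* :func:`window_continuous` — tile every annotated interval (and the
  non-annotated remainder) into consecutive non-overlapping epochs, dropping
  trailing partial epochs; the "continuous case" evaluation of one patient's
  record.
* :func:`window_random` — draw a requested number of non-overlapping epochs
  per class uniformly at random under a seed; the "random case" evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError

SEIZURE = "seizure"
NORMAL = "normal"

__all__ = [
    "SEIZURE",
    "NORMAL",
    "SeizureAnnotation",
    "EEGRecord",
    "Window",
    "window_continuous",
    "window_random",
]


@dataclass(frozen=True)
class SeizureAnnotation:
    """Half-open seizure interval ``[start_s, end_s)`` in record seconds."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid annotation interval [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecord:
    """Multichannel EEG signal (microvolts) with annotations.

    ``signal`` is channel-major: shape ``(n_channels, n_samples)``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    record_id: str = "record"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise ValueError("signal must be a (n_channels >= 1, n_samples) matrix")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for ann in self.annotations:
            if ann.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{ann.start_s}, {ann.end_s}) exceeds record "
                    f"duration {self.duration_s:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Window:
    """One labeled fixed-length epoch; the unit of classification."""

    signal: np.ndarray
    label: str
    record_id: str
    start_s: float
    fs: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.label not in (SEIZURE, NORMAL):
            raise ValueError(f"label must be {SEIZURE!r} or {NORMAL!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _regions_in_samples(
    record: EEGRecord,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Annotated and complement regions as half-open sample ranges."""
    n = record.n_samples
    seiz: list[tuple[int, int]] = []
    for ann in sorted(record.annotations, key=lambda a: a.start_s):
        a = int(round(ann.start_s * record.fs))
        b = min(int(round(ann.end_s * record.fs)), n)
        if b > a:
            seiz.append((a, b))
    normal: list[tuple[int, int]] = []
    cursor = 0
    for a, b in seiz:
        if a > cursor:
            normal.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < n:
        normal.append((cursor, n))
    return seiz, normal


def _cut(record: EEGRecord, start: int, w: int, label: str) -> Window:
    return Window(
        signal=record.signal[:, start : start + w],
        label=label,
        record_id=record.record_id,
        start_s=start / record.fs,
        fs=record.fs,
    )


def window_continuous(record: EEGRecord, window_seconds: float = 10.0) -> list[Window]:
    """Tile the record into consecutive labeled epochs.

    Every annotated interval is tiled from its own start time; the
    non-annotated remainder is tiled from each gap's start. Trailing partial
    epochs are dropped, so a 30-s seizure event yields exactly three 10-s
    seizure epochs. Windows are returned ordered by start time.
    """
    if not window_seconds > 0:
        raise ValueError("window_seconds must be positive")
    w = int(round(window_seconds * record.fs))
    seiz, normal = _regions_in_samples(record)
    out: list[Window] = []
    for regions, label in ((seiz, SEIZURE), (normal, NORMAL)):
        for a, b in regions:
            for j in range((b - a) // w):
                out.append(_cut(record, a + j * w, w, label))
    out.sort(key=lambda win: win.start_s)
    return out


def _place_uniform(
    rng: np.random.Generator, regions: list[tuple[int, int]], w: int, n: int, label: str
) -> list[int]:
    """Draw ``n`` non-overlapping start positions uniformly within regions.

    Capacity of a region of length L is floor(L / w) (exhaustive disjoint
    placement). Slots are allocated across regions by drawing without
    replacement from the pooled slot list; within a region, k starts are
    placed by the order-statistics construction (sorted uniform gaps), which
    samples uniformly among all non-overlapping placements.
    """
    caps = [(b - a) // w for a, b in regions]
    capacity = int(sum(caps))
    if n > capacity:
        raise CapacityError(
            f"requested {n} disjoint {label} windows but only {capacity} fit",
            achievable=capacity,
        )
    slot_owner = np.repeat(np.arange(len(regions)), caps)
    chosen = rng.permutation(slot_owner)[:n]
    starts: list[int] = []
    for r, (a, b) in enumerate(regions):
        k = int(np.sum(chosen == r))
        if k == 0:
            continue
        slack = (b - a) - k * w
        gaps = np.floor(np.sort(rng.uniform(0.0, 1.0, size=k)) * (slack + 1)).astype(int)
        for i in range(k):
            starts.append(a + int(gaps[i]) + i * w)
    return starts


def window_random(
    record: EEGRecord,
    window_seconds: float,
    n_per_class: int,
    seed: int,
) -> list[Window]:
    """Draw ``n_per_class`` seizure and normal epochs at random.

    Epochs are non-overlapping, lie entirely inside (seizure) or entirely
    outside (normal) the annotated intervals, and are reproducible for a
    fixed seed. Raises :class:`CapacityError` stating the achievable count
    when the record cannot supply the request.
    """
    if not window_seconds > 0:
        raise ValueError("window_seconds must be positive")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    w = int(round(window_seconds * record.fs))
    rng = np.random.default_rng(seed)
    seiz, normal = _regions_in_samples(record)
    out: list[Window] = []
    for regions, label in ((seiz, SEIZURE), (normal, NORMAL)):
        for start in _place_uniform(rng, regions, w, n_per_class, label):
            out.append(_cut(record, start, w, label))
    out.sort(key=lambda win: win.start_s)
    return out
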