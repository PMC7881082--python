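"""Generate a synthetic annotated EEG record and cut it into labeled epochs.

The record mimics the structure the pipeline expects: 23 channels at 256 Hz
of band-limited colored noise (SD 50 µV), with a rhythmic spike-wave burst
on three channels during the annotated seizure. The continuous protocol
tiles the seizure interval and the remainder into consecutive 10-s epochs.
"""

from seizurekit import SynthConfig, simulate_record, window_continuous

cfg = SynthConfig(
    duration_s=300.0,
    seizure_intervals=((50.0, 150.0),),
    amplitude_factor=3.0,
    seed=42,
)
record = simulate_record(cfg)
print(f"record: {record.n_channels} channels x {record.n_samples} samples "
      f"({record.duration_s:.0f} s at {record.fs:.0f} Hz)")

windows = window_continuous(record, window_seconds=10.0)
n_seizure = sum(w.label == "seizure" for w in windows)
print(f"epochs: {len(windows)} total, {n_seizure} seizure, "
      f"{len(windows) - n_seizure} normal")
# The 100-s seizure yields exactly 10 consecutive 10-s seizure epochs; the
# two normal stretches (50 s and 150 s) tile into 5 + 15 normal epochs.
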