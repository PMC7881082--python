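"""Rank the channels of one epoch by amplitude variance and keep the top 3.

Uses a published worked example: the per-channel variances of one
23-channel 10-s epoch, whose three largest values sit on channels 2, 21
and 6. Seizure activity raises amplitude (hence variance) on the channels
nearest the focus, so these are the channels worth extracting features from.
"""

from seizurekit import select_top_k

variances = [
    1.44e5, 2.14e5, 9.76e4, 8.92e4, 1.37e5, 1.51e5, 4.16e4, 7.67e4,
    7.23e4, 4.09e4, 2.97e4, 4.10e4, 8.32e4, 4.79e4, 8.25e4, 3.62e4,
    7.22e4, 6.64e4, 9.76e4, 7.76e4, 1.56e5, 2.02e4, 8.25e4,
]

ranking = select_top_k(variances, k=3)
for rank, idx in enumerate(ranking.selected, start=1):
    print(f"#{rank}: CH{idx + 1}  variance {ranking.variances[idx]:.2e} uV^2")
# CH2 (2.14e5) > CH21 (1.56e5) > CH6 (1.51e5): the three channels whose
# features will represent this epoch.
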