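"""Epoch averaging and P300 peak measurement.

Retained epochs are averaged per condition and channel into the subject's
ERP waveform; the P300 is quantified as the maximum of that waveform in
the closed 300-600 ms post-stimulus window (peak amplitude in µV, peak
latency in ms).  Grand averages weight every subject equally regardless of
retained epoch count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmax

from .preproc import EpochSet

__all__ = [
    "SubjectERP",
    "PeakMeasure",
    "average_epochs",
    "grand_average",
    "measure_peak",
    "peaks_to_frame",
]


@dataclass
class SubjectERP:
    """Per-condition, per-channel averaged waveforms of one subject."""

    waveforms: dict[tuple[str, str], np.ndarray]  # (condition, channel) -> µV
    time_ms: np.ndarray
    n_epochs: dict[str, int]  # condition -> retained epochs averaged
    subject_id: str = ""
    group: str = ""

    def __post_init__(self):
        for key, w in self.waveforms.items():
            if len(w) != len(self.time_ms):
                raise ValueError(f"waveform length mismatch for {key}")


@dataclass
class PeakMeasure:
    """P300 peak of one subject x channel x condition."""

    subject_id: str
    channel: str
    condition: str
    amplitude: float  # µV, waveform value at the peak sample
    latency: float  # ms
    group: str = ""


def average_epochs(
    epochs: EpochSet, subject_id: str = "", group: str = ""
) -> SubjectERP:
    """Arithmetic mean of retained epochs per condition and channel."""
    conds = sorted(set(epochs.condition.tolist()))
    waveforms: dict[tuple[str, str], np.ndarray] = {}
    n_epochs: dict[str, int] = {}
    for c in conds:
        mask = epochs.retained & (epochs.condition == c)
        n = int(mask.sum())
        if n < 1:
            raise ValueError(f"no retained epochs for condition {c!r}")
        n_epochs[c] = n
        mean = epochs.data[mask].mean(axis=0)  # channels x time
        for ci, ch in enumerate(epochs.channel_labels):
            waveforms[(c, ch)] = mean[ci]
    return SubjectERP(
        waveforms=waveforms,
        time_ms=epochs.time_ms.copy(),
        n_epochs=n_epochs,
        subject_id=subject_id or epochs.subject_id,
        group=group,
    )


def grand_average(erps: list[SubjectERP]) -> SubjectERP:
    """Unweighted mean over subjects (each subject counts once)."""
    if not erps:
        raise ValueError("no subject ERPs to average")
    t = erps[0].time_ms
    keys = set(erps[0].waveforms)
    for e in erps[1:]:
        if len(e.time_ms) != len(t) or not np.allclose(e.time_ms, t):
            raise ValueError("subject ERPs have mismatching time axes")
        keys &= set(e.waveforms)
    waveforms = {
        k: np.mean([e.waveforms[k] for e in erps], axis=0) for k in sorted(keys)
    }
    n = {c: len(erps) for c in {k[0] for k in keys}}
    return SubjectERP(
        waveforms=waveforms,
        time_ms=t.copy(),
        n_epochs=n,
        subject_id="grand_average",
    )


def measure_peak(
    erp: SubjectERP,
    window_ms: tuple[float, float] = (300.0, 600.0),
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz"),
    local_peaks: bool = False,
) -> list[PeakMeasure]:
    """Measure P300 peak amplitude and latency per channel x condition.

    Default mode takes the global maximum in the closed window (boundary
    samples eligible; earliest sample wins ties).  With ``local_peaks`` the
    largest strict local maximum inside the window is used, falling back to
    the global maximum when no local maximum exists.
    """
    t = erp.time_ms
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} outside the epoch time axis")
    idx_window = np.flatnonzero(mask)
    out = []
    for (cond, ch), w in sorted(erp.waveforms.items()):
        if ch not in channels:
            continue
        seg = w[idx_window]
        if local_peaks:
            rel = argrelmax(seg)[0]
            pick = int(rel[np.argmax(seg[rel])]) if rel.size else int(np.argmax(seg))
        else:
            pick = int(np.argmax(seg))  # argmax returns the earliest tie
        out.append(
            PeakMeasure(
                subject_id=erp.subject_id,
                channel=ch,
                condition=cond,
                amplitude=float(seg[pick]),
                latency=float(t[idx_window[pick]]),
                group=erp.group,
            )
        )
    return out


def peaks_to_frame(peaks: list[PeakMeasure]) -> pd.DataFrame:
    """Long-format table of peak measures (one row per measure)."""
    return pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "group": p.group,
                "channel": p.channel,
                "condition": p.condition,
                "amplitude": p.amplitude,
                "latency": p.latency,
            }
            for p in peaks
        ]
    )
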