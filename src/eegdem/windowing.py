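"""Fixed-length overlapping segmentation of recordings.

Windows are sample-aligned, 0-based and half-open [start, start + w).  The
step between consecutive starts is ``round(w * (1 - overlap))`` samples (for
1 s windows at 500 Hz the 50% and 90% overlaps give exact steps of 250 and
50).  The trailing remainder that cannot fill a whole window is discarded, so
every window has exactly ``window_length_s * fs`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import EEGRecording


@dataclass(frozen=True)
class WindowSpec:
    window_length_s: float = 1.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_length_s * fs))

    def step_samples(self, fs: float) -> int:
        step = int(round(self.window_samples(fs) * (1.0 - self.overlap_fraction)))
        if step < 1:
            raise ValueError(
                f"overlap {self.overlap_fraction} leaves a step < 1 sample "
                f"for {self.window_samples(fs)}-sample windows"
            )
        return step


@dataclass(frozen=True)
class WindowSet:
    """Overlapping segments of one recording: (n_windows, channels, w) array."""

    subject_id: str
    group: str
    fs: float
    channel_names: tuple[str, ...]
    windows: np.ndarray
    window_start_samples: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def window_count(n_samples: int, spec: WindowSpec, fs: float) -> int:
    """Number of full windows: floor((N - w) / step) + 1."""
    w = spec.window_samples(fs)
    if n_samples < w:
        raise ValueError(
            f"recording has {n_samples} samples but one window requires {w}"
        )
    step = spec.step_samples(fs)
    return (n_samples - w) // step + 1


def segment(recording: EEGRecording, spec: WindowSpec) -> WindowSet:
    """Cut a recording into overlapping windows, carrying annotations through."""
    n = recording.n_samples
    w = spec.window_samples(recording.fs)
    count = window_count(n, spec, recording.fs)  # raises if too short
    step = spec.step_samples(recording.fs)
    starts = np.arange(count) * step
    # as_strided-free gather; count*w stays modest at study scale
    idx = starts[:, None] + np.arange(w)[None, :]
    windows = recording.signal[:, idx].transpose(1, 0, 2).copy()
    return WindowSet(
        subject_id=recording.subject_id,
        group=recording.group,
        fs=recording.fs,
        channel_names=recording.montage.channel_names,
        windows=windows,
        window_start_samples=tuple(int(s) for s in starts),
    )
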