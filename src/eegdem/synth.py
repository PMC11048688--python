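"""Synthetic resting-state EEG cohorts with class-conditional spectral structure.

Generates 19-channel, 500 Hz recordings for three groups — healthy controls
(HC), Alzheimer's disease (AD) and frontotemporal dementia (FTD) — with the
spectral signatures the downstream analysis assumes:

* HC: posterior-dominant alpha rhythm over a 1/f background.
* AD: globally raised delta/theta power and reduced alpha ("slowing").
* FTD: raised delta/theta power concentrated over frontal electrodes.

Each signal is 1/f-weighted broadband noise plus band-limited oscillations
(narrowband-filtered Gaussian noise, not pure tones, so complexity measures
vary realistically across windows) plus white sensor noise.  Per-subject gain
jitter makes windows from one subject correlate, which is what makes
subject-leakage checks meaningful.

This is a pipeline-testing device, not a physiological simulator: there is no
dipole forward model, no artifacts, and the group effect sizes are chosen for
learnability, not estimated from patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import MontageSpec, default_montage

GROUPS: tuple[str, ...] = ("AD", "FTD", "HC")

#: Frequency bands (Hz) used for the class-conditional effects.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: Baseline oscillation RMS amplitudes in microvolts (alpha is modulated
#: spatially; see _alpha_spatial_weight).  The profile is oscillation-
#: dominated — strong posterior alpha, substantial delta/theta — so that the
#: group band-power multipliers translate into window-level feature contrasts
#: large enough to support the classification study without being trivial.
_BASE_RMS: dict[str, float] = {"delta": 6.0, "theta": 5.0, "alpha": 10.0, "beta": 1.0}
_PINK_RMS = 2.0     # 1/f background RMS, uV
_SENSOR_RMS = 0.7   # white measurement noise RMS, uV


def default_effects() -> dict[str, dict]:
    """Per-group band-power multipliers and their spatial extent.

    AD: delta/theta power x1.8 and alpha x0.6, globally.
    FTD: delta/theta power x1.6 restricted to frontal electrodes with a
    smooth falloff.  HC is the reference (all multipliers 1).
    """
    return {
        "HC": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "spatial": "global"},
        "AD": {"delta": 1.8, "theta": 1.8, "alpha": 0.6, "beta": 1.0, "spatial": "global"},
        "FTD": {"delta": 1.6, "theta": 1.6, "alpha": 1.0, "beta": 1.0, "spatial": "frontal"},
    }


@dataclass(frozen=True)
class EEGRecording:
    """One subject's labeled multichannel signal (channels x samples, uV)."""

    subject_id: str
    group: str
    fs: float
    signal: np.ndarray
    montage: MontageSpec

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"signal must be (n_channels={self.montage.n_channels}, n_samples), "
                f"got shape {sig.shape}"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite samples")
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    Defaults mirror the reference dataset's composition: 36 AD, 23 FTD and
    29 HC subjects at 500 Hz on the 19-channel 10-20 montage.
    """

    n_per_group: tuple[int, int, int] = (36, 23, 29)  # AD, FTD, HC
    duration_s: float = 60.0
    fs: float = 500.0
    seed: int = 0
    effects: dict = field(default_factory=default_effects)
    pink_exponent: float = 1.0
    gain_jitter: float = 0.10
    montage: MontageSpec = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        if self.duration_s < 2.0:  # at least two 1 s windows
            raise ValueError("duration_s must cover at least two windows (>= 2 s)")
        for group in GROUPS:
            eff = self.effects[group]
            if any(eff[b] <= 0 for b in BANDS):
                raise ValueError("band-power multipliers must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _frontality(montage: MontageSpec) -> np.ndarray:
    """Smooth 0..1 weight concentrated on frontal electrodes (Fp/F rows)."""
    y = montage.positions_array()[:, 1]
    return _sigmoid((y - 0.3) / 0.15)


def _alpha_spatial_weight(montage: MontageSpec) -> np.ndarray:
    """Posterior-dominant alpha amplitude profile (occipital ~1.4, frontal ~0.6)."""
    y = montage.positions_array()[:, 1]
    posteriority = _sigmoid(-(y + 0.2) / 0.2)
    return 0.6 + 0.8 * posteriority


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent-power broadband noise, unit RMS, band-limited to 0.5-45 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shaping = np.zeros_like(freqs)
    in_band = (freqs >= 0.5) & (freqs <= 45.0)
    shaping[in_band] = freqs[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    return x / np.std(x)


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Narrowband Gaussian noise with unit RMS (4th-order Butterworth band-pass).

    The filter warm-up discarded up front is generous (10 s) because the
    0.5 Hz delta edge settles slowly; a short warm-up would leave the first
    seconds of every recording spectrally atypical.
    """
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.normal(size=n + int(10 * fs)))[int(10 * fs):]
    return x / np.std(x)


def generate_recording(spec: CohortSpec, group: str, subject_index: int) -> EEGRecording:
    """Generate one subject's recording; deterministic in (seed, group, index)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    n = int(round(spec.duration_s * spec.fs))
    rng = np.random.default_rng([spec.seed, GROUPS.index(group), subject_index])

    montage = spec.montage
    n_ch = montage.n_channels
    eff = spec.effects[group]
    frontal = _frontality(montage)
    alpha_w = _alpha_spatial_weight(montage)

    # Per-channel band-power multipliers for this group.
    mult = np.ones((n_ch, len(BANDS)))
    for j, band in enumerate(BANDS):
        m = eff[band]
        if eff.get("spatial", "global") == "frontal":
            mult[:, j] = 1.0 + (m - 1.0) * frontal
        else:
            mult[:, j] = m

    gain = 1.0 + spec.gain_jitter * rng.uniform(-1.0, 1.0)  # subject-level gain

    sig = np.empty((n_ch, n), dtype=float)
    for c in range(n_ch):
        x = _PINK_RMS * _pink_noise(rng, n, spec.fs, spec.pink_exponent)
        for j, (band, (lo, hi)) in enumerate(BANDS.items()):
            rms = _BASE_RMS[band] * (alpha_w[c] if band == "alpha" else 1.0)
            rms *= np.sqrt(mult[c, j])  # power multiplier -> amplitude sqrt
            x += rms * _band_noise(rng, n, spec.fs, (lo, hi))
        x += _SENSOR_RMS * rng.normal(size=n)
        sig[c] = gain * x

    return EEGRecording(
        subject_id=f"sub-{group}{subject_index:03d}",
        group=group,
        fs=spec.fs,
        signal=sig,
        montage=montage,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate the full cohort (AD then FTD then HC), reproducible under seed."""
    cohort: list[EEGRecording] = []
    for group, n_subj in zip(GROUPS, spec.n_per_group):
        for i in range(n_subj):
            cohort.append(generate_recording(spec, group, i))
    ids = [r.subject_id for r in cohort]
    assert len(set(ids)) == len(ids)
    return cohort
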