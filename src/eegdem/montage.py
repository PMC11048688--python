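"""Standard 10-20 scalp montage (19 channels) with planar electrode coordinates.

Coordinates are an azimuthal-equidistant ("top view") projection of the
10-20 positions onto the unit head disc: +y is the nasion (front of the
head), +x is the right ear.  They are a plotting convention, adequate for
topographic interpolation; no forward model is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 scalp electrodes of the 10-20 system, in dataset order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "F7", "F3", "T3", "C3", "T5", "P3", "O1",
    "Fz", "Cz", "Pz",
    "Fp2", "F4", "F8", "C4", "T4", "P4", "T6", "O2",
)


def _ring(angle_deg: float, r: float = 0.9) -> tuple[float, float]:
    a = np.deg2rad(angle_deg)
    return (r * np.sin(a), r * np.cos(a))


# Outer 10% ring at r=0.9; inner electrodes on conventional radii.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": _ring(-18), "Fp2": _ring(18),
    "F7": _ring(-54), "F8": _ring(54),
    "T3": _ring(-90), "T4": _ring(90),
    "T5": _ring(-126), "T6": _ring(126),
    "O1": _ring(-162), "O2": _ring(162),
    "Fz": (0.0, 0.45), "Cz": (0.0, 0.0), "Pz": (0.0, -0.45),
    "F3": (-0.36, 0.49), "F4": (0.36, 0.49),
    "C3": (-0.45, 0.0), "C4": (0.45, 0.0),
    "P3": (-0.36, -0.49), "P4": (0.36, -0.49),
}


@dataclass(frozen=True)
class MontageSpec:
    """An ordered electrode montage with 2-D positions in the unit head disc."""

    channel_names: tuple[str, ...] = CHANNELS_1020
    positions_2d: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.positions_2d is None:
            object.__setattr__(
                self,
                "positions_2d",
                tuple(_POSITIONS[name] for name in self.channel_names),
            )
        names = self.channel_names
        if len(names) != 19:
            raise ValueError(f"montage must have exactly 19 channels, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if len(self.positions_2d) != len(names):
            raise ValueError("positions_2d length must match channel_names")
        for name, (x, y) in zip(names, self.positions_2d):
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"electrode {name} lies outside the unit head disc")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def positions_array(self) -> np.ndarray:
        """Positions as an (n_channels, 2) float array."""
        return np.asarray(self.positions_2d, dtype=float)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


def default_montage() -> MontageSpec:
    """The 19-channel 10-20 montage used throughout."""
    return MontageSpec()
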