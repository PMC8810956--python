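"""Hounsfield-unit windowing and three-channel composition.

A CT window maps the HU interval ``[WL - WW/2, WL + WW/2]`` linearly onto
8-bit gray levels, clamping outside the interval — the standard radiology
display transform.  The classifier consumes three co-registered windowings
of the same arterial-phase volume: a wide liver window (red), a narrow
ablation window straddling parenchymal HU (green), and a narrow tumor
window that saturates only for arterially enhancing tissue (blue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_io import CTVolume

__all__ = [
    "WindowSetting",
    "MultiChannelVolume",
    "LIVER_WINDOW",
    "ABLATION_WINDOW",
    "TUMOR_WINDOW",
    "DEFAULT_WINDOWS",
    "apply_window",
    "compose_channels",
]


@dataclass(frozen=True)
class WindowSetting:
    """A display window: center ``level`` (WL) and span ``width`` (WW), in HU."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


LIVER_WINDOW = WindowSetting(level=60, width=400)
ABLATION_WINDOW = WindowSetting(level=80, width=60)
TUMOR_WINDOW = WindowSetting(level=120, width=40)
#: red = liver, green = ablation, blue = tumor
DEFAULT_WINDOWS = (LIVER_WINDOW, ABLATION_WINDOW, TUMOR_WINDOW)


@dataclass
class MultiChannelVolume:
    """Three aligned 8-bit windowed views of one CT volume.

    ``channels`` has shape ``(3, nx, ny, nz)`` (red, green, blue); the
    affine is inherited unchanged from the source volume, since the
    channels are re-windowings of the same scan and need no resampling.
    """

    channels: np.ndarray
    affine: np.ndarray
    settings: tuple[WindowSetting, WindowSetting, WindowSetting]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError("channels must have shape (3, nx, ny, nz)")
        if self.channels.dtype != np.uint8:
            raise ValueError("channels must be 8-bit")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]  # type: ignore[return-value]


def _window_scalarwise(hu: np.ndarray, w: WindowSetting) -> np.ndarray:
    # round-half-up via floor(x + 0.5); np.round would round half to even
    scaled = 255.0 * (hu - w.level + w.width / 2.0) / w.width
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def apply_window(volume, w: WindowSetting) -> np.ndarray:
    """Map HU values to 8-bit gray levels under window ``w``.

    Accepts a :class:`~ltpdetect.ct_io.CTVolume` or a bare HU array and
    returns a uint8 array of the same shape.  The map is monotone
    non-decreasing in HU and clamps at the window edges.
    """
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    return _window_scalarwise(np.asarray(hu, dtype=np.float64), w)


def compose_channels(volume: CTVolume, settings=DEFAULT_WINDOWS) -> MultiChannelVolume:
    """Stack three windowed views of ``volume`` into a MultiChannelVolume."""
    settings = tuple(settings)
    if len(settings) != 3:
        raise ValueError(f"exactly three window settings required, got {len(settings)}")
    channels = np.stack([apply_window(volume, w) for w in settings], axis=0)
    return MultiChannelVolume(channels, np.asarray(volume.affine).copy(), settings)
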