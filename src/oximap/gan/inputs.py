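"""Three-channel network input assembly.

Channels 1 and 2 are the flat-field-corrected single-phase patterned
frames at the two wavelengths (sample frame divided by the reference
phantom's planar frame).  Channel 3 encodes session drift: the reference
phantom's AC/DC modulation ratio at each wavelength, alternated per
pixel parity in a checkerboard ((row + col) even pixels carry the
shorter wavelength's ratio).  All channels are affine-mapped to [-1, 1]
by a fixed, documented normalization scale: ``v -> 2 * v / scale - 1``,
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..phantoms import ReferencePhantom, StructuredFrame

__all__ = ["NetworkInput", "assemble_input", "normalize_channel", "checkerboard"]

DEFAULT_SCALE = 1.0


@dataclass
class NetworkInput:
    """(3, H, W) array in [-1, 1] plus assembly provenance."""

    channels: np.ndarray
    wavelengths: tuple
    scale: float

    def __post_init__(self):
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("network input must be (3, H, W)")
        if np.any(np.abs(self.channels) > 1.0 + 1e-12):
            raise ValueError("network input outside [-1, 1]")


def normalize_channel(v: np.ndarray, scale: float) -> np.ndarray:
    """Affine map [0, scale] -> [-1, 1], clipped."""
    return np.clip(2.0 * v / scale - 1.0, -1.0, 1.0)


def checkerboard(shape, value_even: float, value_odd: float) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    even = (rows + cols) % 2 == 0
    return np.where(even, value_even, value_odd)


def assemble_input(
    frame_a: StructuredFrame,
    frame_b: StructuredFrame,
    ref: ReferencePhantom,
    scale: float = DEFAULT_SCALE,
) -> NetworkInput:
    """Build the conditioning image from two snapshot frames.

    ``frame_a``/``frame_b`` are single-phase patterned frames at the two
    wavelengths; the shorter wavelength populates channel 1 and the even
    checkerboard parity.
    """
    frames = sorted((frame_a, frame_b), key=lambda f: f.wavelength)
    shape = frames[0].intensity.shape
    if frames[1].intensity.shape != shape:
        raise ValueError("snapshot frames must share geometry")
    channels = []
    ratios = []
    for frame in frames:
        wl = frame.wavelength
        if (wl, 0.0) not in ref.rd_model:
            raise KeyError(f"reference lacks wavelength {wl} nm")
        planar = ref.planar_frame(wl)
        with np.errstate(divide="ignore", invalid="ignore"):
            flat = np.where(planar > 0, frame.intensity / planar, 0.0)
        channels.append(normalize_channel(flat, scale))
        mac, mdc = ref.modulation(wl, frame.fx)
        ratios.append(float(np.mean(mac) / np.mean(mdc)))
    board = checkerboard(shape, ratios[0], ratios[1])
    channels.append(normalize_channel(board, scale))
    return NetworkInput(
        channels=np.stack(channels),
        wavelengths=(frames[0].wavelength, frames[1].wavelength),
        scale=scale,
    )
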