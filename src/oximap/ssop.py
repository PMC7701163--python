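"""Single-snapshot demodulation by anisotropic Fourier filtering.

One patterned frame carries the planar response at baseband and the
modulated response on sidebands at the carrier frequency.  The DC
magnitude is recovered with a sine-profile low-pass along the carrier
axis (unit gain at zero frequency); the AC magnitude is recovered by
isolating the positive sideband with a Blackman-profile band-pass
centered on the carrier and doubling the magnitude of its inverse
transform (analytic-signal demodulation).  Both filters act on the
carrier-axis frequency only and are uniform across the orthogonal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromophores import ChromophoreBasis
from .phantoms import ReferencePhantom, StructuredFrame
from .sfdi import (
    ModulationPair,
    ReflectanceLUT,
    StO2Map,
    calibrate,
    compute_sto2,
    fit_chromophores,
    invert_lut,
)

__all__ = ["SsopFilterConfig", "ssop_demodulate", "ssop_sto2", "interior_mask"]


@dataclass(frozen=True)
class SsopFilterConfig:
    """Cutoffs expressed as fractions of the carrier frequency."""

    lowpass_cutoff: float = 0.5
    highpass_width: float = 1.0
    guard_periods: float = 2.0

    def __post_init__(self):
        if not (0.0 < self.lowpass_cutoff < 1.0):
            raise ValueError("lowpass cutoff must lie in (0, 1)")
        if self.highpass_width <= 0:
            raise ValueError("highpass width must be positive")


def _sine_lowpass(freqs: np.ndarray, cutoff: float) -> np.ndarray:
    """Half-sine profile: 1 at DC, 0 at the cutoff, 0 beyond."""
    h = np.cos(0.5 * np.pi * np.abs(freqs) / cutoff)
    return np.where(np.abs(freqs) < cutoff, h, 0.0)


def _blackman_bandpass(freqs: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Blackman profile over [center - w, center + w]; zero elsewhere,
    in particular on all negative frequencies (single-sideband)."""
    t = (freqs - (center - half_width)) / (2.0 * half_width)
    window = 0.42 - 0.5 * np.cos(2.0 * np.pi * t) + 0.08 * np.cos(4.0 * np.pi * t)
    inside = (t > 0.0) & (t < 1.0) & (freqs > 0.0)
    return np.where(inside, window, 0.0)


def ssop_demodulate(
    frame: StructuredFrame,
    pixel_pitch: float,
    cfg: SsopFilterConfig = SsopFilterConfig(),
) -> ModulationPair:
    """Recover (MAC, MDC) from a single patterned frame.

    The frame's carrier must be strictly positive and representable:
    below Nyquist and with at least ~8 periods across the image width.
    """
    if frame.fx <= 0:
        raise ValueError("snapshot demodulation requires a patterned frame (fx > 0)")
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    img = np.asarray(frame.intensity, dtype=float)
    n_cols = img.shape[1]
    f_carrier = frame.fx * pixel_pitch  # cycles / pixel
    if f_carrier >= 0.5:
        raise ValueError("carrier frequency above Nyquist for this pixel pitch")
    if f_carrier * n_cols < 8.0:
        raise ValueError("image spans fewer than 8 carrier periods")

    freqs = np.fft.fftfreq(n_cols)  # cycles / pixel, along the carrier axis
    spectrum = np.fft.fft(img, axis=1)

    h_lp = _sine_lowpass(freqs, cfg.lowpass_cutoff * f_carrier)
    mdc = np.fft.ifft(spectrum * h_lp[None, :], axis=1).real

    h_hp = _blackman_bandpass(freqs, f_carrier, cfg.highpass_width * f_carrier)
    mac = 2.0 * np.abs(np.fft.ifft(spectrum * h_hp[None, :], axis=1))

    return ModulationPair(
        mac=np.clip(mac, 0.0, None),
        mdc=np.clip(mdc, 0.0, None),
        wavelength=frame.wavelength,
        fx=frame.fx,
    )


def interior_mask(shape, fx: float, pixel_pitch: float, guard_periods: float = 2.0):
    """Mask excluding a guard band of carrier periods at the left/right
    edges, where windowed demodulation is unspecified."""
    period_px = 1.0 / (fx * pixel_pitch)
    guard = int(np.ceil(guard_periods * period_px))
    mask = np.zeros(shape, dtype=bool)
    if 2 * guard < shape[1]:
        mask[:, guard : shape[1] - guard] = True
    return mask


def ssop_sto2(
    frame_a: StructuredFrame,
    frame_b: StructuredFrame,
    ref: ReferencePhantom,
    lut: ReflectanceLUT,
    basis: ChromophoreBasis,
    cfg: SsopFilterConfig = SsopFilterConfig(),
    min_total: float = 1e-6,
    return_details: bool = False,
) -> StO2Map:
    """Snapshot pipeline: Fourier demodulation per wavelength, reference
    calibration, table inversion, two-wavelength chromophore fit.

    The reference phantom is demodulated conventionally (three-phase) at
    the carrier frequency; its triplet MDC matches the snapshot low-pass
    output (both are half the planar level times gain).
    """
    if frame_a.intensity.shape != frame_b.intensity.shape:
        raise ValueError("snapshot frames must share geometry")
    optics = []
    for frame in (frame_a, frame_b):
        pair = ssop_demodulate(frame, ref.pixel_pitch, cfg)
        mac_ref, mdc_ref = ref.modulation(frame.wavelength, frame.fx)
        rd_dc = calibrate(pair.mdc, mdc_ref, ref.rd_model[(frame.wavelength, 0.0)])
        rd_ac = calibrate(pair.mac, mac_ref, ref.rd_model[(frame.wavelength, frame.fx)])
        optics.append(invert_lut(rd_dc, rd_ac, lut, wavelength=frame.wavelength))
    conc = fit_chromophores(optics, basis)
    sto2 = compute_sto2(conc, min_total=min_total)
    sto2.valid &= np.all([m.valid for m in optics], axis=0)
    if return_details:
        return sto2, optics, conc
    return sto2
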