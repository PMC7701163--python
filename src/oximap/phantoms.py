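"""Synthetic tissue scenes and rendered structured-illumination
acquisitions.

A scene is defined by per-pixel chromophore concentrations plus a
scattering power law ``musp(lam) = a * (lam / lam0)**(-b)`` with
``lam0 = 800 nm``.  Rendering projects a unit-modulation sinusoid along
the image x axis: for each (wavelength, frequency, phase) the clean
intensity is ``gain/2 * (Rd_dc + Rd_fx * cos(2*pi*fx*x_mm + phase))``;
planar (fx = 0) frames carry ``gain * Rd_dc`` because a phase offset is
a spatial shift of the pattern and shifts nothing at zero frequency.
Noise (relative additive Gaussian, optional Poisson) is seeded and
recorded in the stack provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .chromophores import DEOXY, OXY, ChromophoreBasis
from .diffusion import diffuse_reflectance
from .sfdi import OpticalPropertyMap, demodulate_three_phase

__all__ = [
    "SCATTER_REFERENCE_NM",
    "NoiseModel",
    "AcquisitionProtocol",
    "ground_truth_protocol",
    "snapshot_protocol",
    "PhantomScene",
    "StructuredFrame",
    "AcquisitionStack",
    "ReferencePhantom",
    "scene_optical_properties",
    "render_acquisition",
    "make_reference",
    "OcclusionTimeline",
    "simulate_occlusion_series",
    "random_scene",
    "homogeneous_scene",
]

SCATTER_REFERENCE_NM = 800.0
_KEY_DECIMALS = 9


def _key(wavelength, fx, phase):
    return (
        round(float(wavelength), _KEY_DECIMALS),
        round(float(fx), _KEY_DECIMALS),
        round(float(phase), _KEY_DECIMALS),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise (sigma relative to each frame's mean clean
    level) plus optional Poisson shot noise at ``photons`` counts per
    unit."""

    sigma_rel: float = 0.0
    shot: bool = False
    photons: float = 1e4
    seed: int = 0


@dataclass(frozen=True)
class AcquisitionProtocol:
    wavelengths: Tuple[float, ...]
    spatial_frequencies: Tuple[float, ...]
    phases: Tuple[float, ...]
    gain: float = 1000.0
    noise: NoiseModel = NoiseModel()

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        object.__setattr__(
            self, "spatial_frequencies", tuple(float(f) for f in self.spatial_frequencies)
        )
        object.__setattr__(self, "phases", tuple(float(p) for p in self.phases))
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.wavelengths) * len(self.spatial_frequencies) * len(self.phases)


def ground_truth_protocol(**overrides) -> AcquisitionProtocol:
    """Default multi-frame protocol: 2 frequencies x 3 phases x 4 wavelengths."""
    kwargs = dict(
        wavelengths=(659.0, 691.0, 731.0, 851.0),
        spatial_frequencies=(0.0, 0.2),
        phases=(0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0),
    )
    kwargs.update(overrides)
    return AcquisitionProtocol(**kwargs)


def snapshot_protocol(**overrides) -> AcquisitionProtocol:
    """Single-snapshot protocol: one patterned frame at each of two wavelengths."""
    kwargs = dict(
        wavelengths=(659.0, 851.0),
        spatial_frequencies=(0.2,),
        phases=(0.0,),
    )
    kwargs.update(overrides)
    return AcquisitionProtocol(**kwargs)


@dataclass
class PhantomScene:
    """Ground-truth optics of a synthetic sample.

    ``conc_maps`` holds one non-negative concentration image per
    chromophore name; scattering follows the power law in ``a``/``b``
    anchored at :data:`SCATTER_REFERENCE_NM`.
    """

    conc_maps: Dict[str, np.ndarray]
    scatter_amplitude: np.ndarray
    scatter_power: np.ndarray
    pixel_pitch: float
    refractive_index: float = 1.4
    mask: np.ndarray | None = None
    scene_id: str = "scene"

    def __post_init__(self):
        shapes = {m.shape for m in self.conc_maps.values()}
        shapes |= {self.scatter_amplitude.shape, self.scatter_power.shape}
        if len(shapes) != 1:
            raise ValueError("all scene maps must share one shape")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        for name, cmap in self.conc_maps.items():
            if np.any(cmap < 0):
                raise ValueError(f"negative concentration in {name!r}")
        if np.any(self.scatter_amplitude <= 0) or np.any(self.scatter_power < 0):
            raise ValueError("invalid scattering parameters")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.scatter_amplitude.shape

    @property
    def sto2(self) -> np.ndarray:
        """Oxygen saturation derived from the hemoglobin maps (NaN where
        total hemoglobin is zero)."""
        oxy = self.conc_maps[OXY]
        total = oxy + self.conc_maps[DEOXY]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(total > 0, oxy / np.where(total > 0, total, 1.0), np.nan)

    def musp(self, wavelength: float) -> np.ndarray:
        return self.scatter_amplitude * (wavelength / SCATTER_REFERENCE_NM) ** (
            -self.scatter_power
        )


@dataclass
class StructuredFrame:
    intensity: np.ndarray
    wavelength: float
    fx: float
    phase: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("frame intensities must be finite and non-negative")


@dataclass
class AcquisitionStack:
    """Ordered structured frames keyed by (wavelength, fx, phase)."""

    frames: List[StructuredFrame]
    provenance: dict = field(default_factory=dict)
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {}
        for i, f in enumerate(self.frames):
            k = _key(f.wavelength, f.fx, f.phase)
            if k in self._index:
                raise ValueError(f"duplicate frame key {k}")
            self._index[k] = i

    def __len__(self):
        return len(self.frames)

    def has(self, wavelength, fx, phase) -> bool:
        return _key(wavelength, fx, phase) in self._index

    def get(self, wavelength, fx, phase) -> StructuredFrame:
        try:
            return self.frames[self._index[_key(wavelength, fx, phase)]]
        except KeyError:
            raise KeyError(f"no frame at {(wavelength, fx, phase)}") from None

    def triplet(self, wavelength, fx) -> List[StructuredFrame]:
        out = [
            self.frames[i]
            for k, i in sorted(self._index.items(), key=lambda kv: kv[0][2])
            if k[0] == round(float(wavelength), _KEY_DECIMALS)
            and k[1] == round(float(fx), _KEY_DECIMALS)
        ]
        if not out:
            raise KeyError(f"no frames at wavelength {wavelength}, fx {fx}")
        return out

    def wavelengths(self):
        return sorted({k[0] for k in self._index})

    def frequencies(self):
        return sorted({k[1] for k in self._index})


def scene_optical_properties(
    scene: PhantomScene, basis: ChromophoreBasis, wavelength: float
) -> OpticalPropertyMap:
    """Forward absorption mixture and scattering power law at one wavelength."""
    eps = basis.row(wavelength)  # raises on unknown wavelength
    mua = np.zeros(scene.shape)
    for j, name in enumerate(basis.names):
        if name not in scene.conc_maps:
            raise KeyError(f"scene lacks a concentration map for {name!r}")
        mua += eps[j] * scene.conc_maps[name]
    musp = scene.musp(wavelength)
    valid = scene.mask & (mua > 0) & (musp > 0)
    return OpticalPropertyMap(mua=mua, musp=musp, wavelength=wavelength, valid=valid)


def _pattern(shape, pixel_pitch, fx, phase):
    if fx == 0.0:
        # a phase offset shifts the pattern; a uniform pattern is shift-invariant
        return None
    x_mm = np.arange(shape[1]) * pixel_pitch
    return np.cos(2.0 * np.pi * fx * x_mm + phase)[None, :]


def _render_frames(rd_of, shape, pixel_pitch, protocol, rng):
    """Shared renderer: ``rd_of(wavelength, fx)`` returns an Rd image."""
    noise = protocol.noise
    frames = []
    for wl in protocol.wavelengths:
        rd_dc = rd_of(wl, 0.0)
        for fx in protocol.spatial_frequencies:
            rd_fx = rd_of(wl, fx)
            for phase in protocol.phases:
                pat = _pattern(shape, pixel_pitch, fx, phase)
                if pat is None:
                    clean = protocol.gain * rd_dc * np.ones(shape)
                else:
                    clean = 0.5 * protocol.gain * (rd_dc + rd_fx * pat) * np.ones(shape)
                img = clean
                if noise.shot:
                    img = rng.poisson(np.clip(img, 0, None) * noise.photons) / noise.photons
                if noise.sigma_rel > 0:
                    # sigma scales with each frame's own mean clean level
                    sigma = noise.sigma_rel * float(np.mean(clean))
                    img = img + rng.normal(0.0, sigma, size=shape)
                frames.append(
                    StructuredFrame(
                        intensity=np.clip(img, 0.0, None),
                        wavelength=wl,
                        fx=fx,
                        phase=phase,
                    )
                )
    return frames


def render_acquisition(
    scene: PhantomScene, basis: ChromophoreBasis, protocol: AcquisitionProtocol
) -> AcquisitionStack:
    """Render the full structured-illumination stack for a scene."""
    rng = np.random.default_rng(protocol.noise.seed)
    rd_cache: Dict[Tuple[float, float], np.ndarray] = {}

    def rd_of(wl, fx):
        k = (wl, fx)
        if k not in rd_cache:
            props = scene_optical_properties(scene, basis, wl)
            rd_cache[k] = diffuse_reflectance(
                props.mua, props.musp, fx, scene.refractive_index
            )
        return rd_cache[k]

    frames = _render_frames(rd_of, scene.shape, scene.pixel_pitch, protocol, rng)
    stack = AcquisitionStack(
        frames=frames,
        provenance={
            "scene_id": scene.scene_id,
            "pixel_pitch": scene.pixel_pitch,
            "protocol": {
                "wavelengths": list(protocol.wavelengths),
                "spatial_frequencies": list(protocol.spatial_frequencies),
                "phases": list(protocol.phases),
                "gain": protocol.gain,
            },
            "seed": protocol.noise.seed,
        },
    )
    if len(stack) != protocol.n_frames:
        raise RuntimeError("frame count does not match protocol")
    return stack


@dataclass
class ReferencePhantom:
    """Homogeneous calibration phantom: known optics, rendered stack, and
    model-predicted reflectance at every (wavelength, fx)."""

    optics: Dict[float, Tuple[float, float]]
    stack: AcquisitionStack
    rd_model: Dict[Tuple[float, float], float]
    pixel_pitch: float

    def modulation(self, wavelength, fx):
        """(MAC, MDC) of the fx triplet by conventional demodulation."""
        frames = self.stack.triplet(wavelength, fx)
        return demodulate_three_phase(*(f.intensity for f in frames))

    def planar_frame(self, wavelength) -> np.ndarray:
        return self.stack.triplet(wavelength, 0.0)[0].intensity


def make_reference(
    optics: Dict[float, Tuple[float, float]],
    protocol: AcquisitionProtocol,
    shape: Tuple[int, int] = (64, 64),
    pixel_pitch: float = 0.5,
    n_index: float = 1.4,
    drift: float = 1.0,
) -> ReferencePhantom:
    """Render a homogeneous reference phantom under ``protocol``.

    ``optics`` maps wavelength -> (mua, musp); every protocol wavelength
    must be present.  ``drift`` multiplies the gain to emulate a slow
    system change between the reference and sample sessions.
    """
    missing = [w for w in protocol.wavelengths if float(w) not in optics]
    if missing:
        raise ValueError(f"reference optics missing wavelengths {missing}")
    if drift <= 0:
        raise ValueError("drift factor must be positive")
    proto = replace(protocol, gain=protocol.gain * drift)
    rng = np.random.default_rng(proto.noise.seed)

    rd_model = {}
    for wl in proto.wavelengths:
        mua, musp = optics[float(wl)]
        for fx in set(proto.spatial_frequencies) | {0.0}:
            rd_model[(float(wl), float(fx))] = diffuse_reflectance(mua, musp, fx, n_index)
    for rd in rd_model.values():
        if not (0.0 < rd < 1.0):
            raise ValueError("reference model reflectance outside (0, 1)")

    def rd_of(wl, fx):
        return np.full(shape, rd_model[(float(wl), float(fx))])

    frames = _render_frames(rd_of, shape, pixel_pitch, proto, rng)
    stack = AcquisitionStack(frames=frames, provenance={"scene_id": "reference"})
    return ReferencePhantom(
        optics=optics, stack=stack, rd_model=rd_model, pixel_pitch=pixel_pitch
    )


# ---------------------------------------------------------------------------
# scene generators


def _smooth_field(rng, shape, low, high, smooth_px=8.0):
    noise = gaussian_filter(rng.standard_normal(shape), smooth_px)
    span = noise.max() - noise.min()
    unit = (noise - noise.min()) / span if span > 0 else np.full(shape, 0.5)
    return low + (high - low) * unit


def random_scene(
    shape=(64, 64),
    pixel_pitch: float = 0.5,
    rng=None,
    hbt_range=(0.02, 0.06),
    sto2_range=(0.35, 0.95),
    scatter_amplitude_range=(0.8, 1.6),
    scatter_power_range=(0.6, 1.4),
    smooth_px: float = 8.0,
    scene_id: str = "random",
) -> PhantomScene:
    """Smooth random tissue-like scene (hemoglobin in mM)."""
    rng = np.random.default_rng(rng)
    hbt = _smooth_field(rng, shape, *hbt_range, smooth_px)
    sto2 = _smooth_field(rng, shape, *sto2_range, smooth_px)
    return PhantomScene(
        conc_maps={OXY: hbt * sto2, DEOXY: hbt * (1.0 - sto2)},
        scatter_amplitude=_smooth_field(rng, shape, *scatter_amplitude_range, smooth_px),
        scatter_power=_smooth_field(rng, shape, *scatter_power_range, smooth_px),
        pixel_pitch=pixel_pitch,
        scene_id=scene_id,
    )


def homogeneous_scene(
    shape=(64, 64),
    pixel_pitch: float = 0.5,
    hbt: float = 0.04,
    sto2: float = 0.7,
    scatter_amplitude: float = 1.1,
    scatter_power: float = 1.0,
    scene_id: str = "homogeneous",
) -> PhantomScene:
    ones = np.ones(shape)
    return PhantomScene(
        conc_maps={OXY: hbt * sto2 * ones, DEOXY: hbt * (1.0 - sto2) * ones},
        scatter_amplitude=scatter_amplitude * ones,
        scatter_power=scatter_power * ones,
        pixel_pitch=pixel_pitch,
        scene_id=scene_id,
    )


# ---------------------------------------------------------------------------
# occlusion dynamics


@dataclass(frozen=True)
class OcclusionTimeline:
    """Piecewise saturation trajectory for a cuff-occlusion analogue.

    Baseline plateau, single-exponential desaturation toward
    ``occluded_sto2`` during occlusion, then recovery with a transient
    overshoot of ``overshoot`` above baseline that settles back.  Total
    hemoglobin is held constant throughout.
    """

    baseline_s: float = 60.0
    occlusion_s: float = 180.0
    release_s: float = 150.0
    dt_s: float = 5.0
    occluded_sto2: float = 0.35
    overshoot: float = 0.05
    tau_desaturation_s: float = 60.0
    tau_recovery_s: float = 8.0
    tau_settle_s: float = 60.0

    def __post_init__(self):
        if not (0.0 <= self.occluded_sto2 <= 1.0):
            raise ValueError("occluded saturation target outside [0, 1]")
        if min(self.tau_desaturation_s, self.tau_recovery_s, self.tau_settle_s) <= 0:
            raise ValueError("time constants must be positive")

    def trajectory(self, t: np.ndarray, s0: float) -> np.ndarray:
        if not (0.0 <= s0 <= 1.0):
            raise ValueError("baseline saturation outside [0, 1]")
        t = np.asarray(t, dtype=float)
        if self.occlusion_s == 0.0:
            return np.full(t.shape, s0)  # identity timeline
        t1 = self.baseline_s
        t2 = self.baseline_s + self.occlusion_s
        s = np.full(t.shape, s0)
        occ = (t > t1) & (t <= t2)
        s[occ] = self.occluded_sto2 + (s0 - self.occluded_sto2) * np.exp(
            -(t[occ] - t1) / self.tau_desaturation_s
        )
        s_end = (
            self.occluded_sto2
            + (s0 - self.occluded_sto2) * np.exp(-self.occlusion_s / self.tau_desaturation_s)
            if self.occlusion_s > 0
            else s0
        )
        rel = t > t2
        if np.any(rel):
            peak = min(1.0, s0 + self.overshoot)
            dt = t[rel] - t2
            s[rel] = (
                peak
                + (s_end - peak) * np.exp(-dt / self.tau_recovery_s)
                + (s0 - peak) * (1.0 - np.exp(-dt / self.tau_settle_s))
            )
        return np.clip(s, 0.0, 1.0)


def simulate_occlusion_series(
    scene: PhantomScene,
    timeline: OcclusionTimeline,
    region: np.ndarray | None = None,
) -> List[Tuple[float, PhantomScene]]:
    """Time series of scenes whose region saturation follows the timeline.

    Within ``region`` the per-pixel saturation is shifted by the
    trajectory delta (preserving spatial texture and total hemoglobin);
    pixels outside the region are unchanged.
    """
    if region is None:
        region = np.ones(scene.shape, dtype=bool)
    if not np.any(region):
        raise ValueError("empty occlusion region")
    base_sto2 = scene.sto2
    s0 = float(np.nanmean(np.where(region, base_sto2, np.nan)))
    total_t = timeline.baseline_s + timeline.occlusion_s + timeline.release_s
    times = np.arange(0.0, total_t + 1e-9, timeline.dt_s)
    traj = timeline.trajectory(times, s0)

    hbt = scene.conc_maps[OXY] + scene.conc_maps[DEOXY]
    series = []
    for t, s_t in zip(times, traj):
        sto2_t = np.where(region, np.clip(base_sto2 + (s_t - s0), 0.0, 1.0), base_sto2)
        sto2_t = np.where(np.isnan(sto2_t), 0.0, sto2_t)
        series.append(
            (
                float(t),
                PhantomScene(
                    conc_maps={OXY: hbt * sto2_t, DEOXY: hbt * (1.0 - sto2_t)},
                    scatter_amplitude=scene.scatter_amplitude,
                    scatter_power=scene.scatter_power,
                    pixel_pitch=scene.pixel_pitch,
                    refractive_index=scene.refractive_index,
                    mask=scene.mask,
                    scene_id=f"{scene.scene_id}_t{t:07.1f}",
                ),
            )
        )
    return series
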