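"""Synthetic training data for the snapshot-to-saturation network.

Each sample is one random phantom scene rendered under the snapshot
protocol (one patterned frame per wavelength), assembled into the
three-channel conditioning image; the target is the scene's true
saturation mapped linearly to [-1, 1].
"""

from __future__ import annotations

import numpy as np

from ..chromophores import ChromophoreBasis, load_default_basis
from ..phantoms import (
    ReferencePhantom,
    ground_truth_protocol,
    make_reference,
    random_scene,
    render_acquisition,
    snapshot_protocol,
)
from .inputs import DEFAULT_SCALE, assemble_input

__all__ = ["default_reference", "make_patch_dataset", "sto2_to_target", "target_to_sto2"]

DEFAULT_REFERENCE_OPTICS = {
    659.0: (0.018, 1.2),
    691.0: (0.016, 1.15),
    731.0: (0.015, 1.1),
    851.0: (0.012, 1.0),
}


def default_reference(shape=(64, 64), pixel_pitch=0.5, seed=0) -> ReferencePhantom:
    protocol = ground_truth_protocol()
    protocol = type(protocol)(
        wavelengths=protocol.wavelengths,
        spatial_frequencies=protocol.spatial_frequencies,
        phases=protocol.phases,
        gain=protocol.gain,
        noise=protocol.noise.__class__(seed=seed),
    )
    return make_reference(
        DEFAULT_REFERENCE_OPTICS, protocol, shape=shape, pixel_pitch=pixel_pitch
    )


def sto2_to_target(sto2: np.ndarray) -> np.ndarray:
    """[0, 1] saturation to the generator's (-1, 1) output coding."""
    return 2.0 * np.clip(sto2, 0.0, 1.0) - 1.0


def target_to_sto2(target: np.ndarray) -> np.ndarray:
    return np.clip((target + 1.0) / 2.0, 0.0, 1.0)


def make_patch_dataset(
    n_patches: int,
    patch_size: int = 64,
    pixel_pitch: float = 0.5,
    seed: int = 0,
    basis: ChromophoreBasis | None = None,
    reference: ReferencePhantom | None = None,
    noise_sigma: float = 0.0,
    scale: float = DEFAULT_SCALE,
):
    """List of ((3, S, S) input, (1, S, S) target) training pairs.

    Scene randomness, rendering noise seeds, and the reference phantom
    all derive from ``seed``.
    """
    rng = np.random.default_rng(seed)
    basis = basis if basis is not None else load_default_basis()
    shape = (patch_size, patch_size)
    if reference is None:
        reference = default_reference(shape=shape, pixel_pitch=pixel_pitch, seed=seed)
    pairs = []
    for _ in range(n_patches):
        scene = random_scene(
            shape=shape,
            pixel_pitch=pixel_pitch,
            rng=rng,
            smooth_px=patch_size / 8.0,
        )
        protocol = snapshot_protocol(
            noise=type(ground_truth_protocol().noise)(
                sigma_rel=noise_sigma, seed=int(rng.integers(2**31))
            )
        )
        stack = render_acquisition(scene, basis, protocol)
        frame_a = stack.get(659.0, 0.2, 0.0)
        frame_b = stack.get(851.0, 0.2, 0.0)
        net_in = assemble_input(frame_a, frame_b, reference, scale=scale)
        target = sto2_to_target(np.nan_to_num(scene.sto2, nan=0.0))[None]
        pairs.append((net_in.channels, target))
    return pairs
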