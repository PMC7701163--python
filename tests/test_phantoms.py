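import numpy as np
import pytest

from oximap.chromophores import DEOXY, OXY
from oximap.diffusion import diffuse_reflectance
from oximap.phantoms import (
    AcquisitionStack,
    NoiseModel,
    OcclusionTimeline,
    PhantomScene,
    ground_truth_protocol,
    homogeneous_scene,
    make_reference,
    random_scene,
    render_acquisition,
    scene_optical_properties,
    simulate_occlusion_series,
    snapshot_protocol,
)
from oximap.sfdi import calibrate, demodulate_three_phase
from tests.conftest import REFERENCE_OPTICS


def _zero_scene(shape=(8, 8)):
    zeros = np.zeros(shape)
    return PhantomScene(
        conc_maps={OXY: zeros.copy(), DEOXY: zeros.copy()},
        scatter_amplitude=np.ones(shape),
        scatter_power=np.ones(shape),
        pixel_pitch=0.5,
    )


class TestSceneOpticalProperties:
    def test_zero_concentration_flagged_invalid(self, basis):
        props = scene_optical_properties(_zero_scene(), basis, 659.0)
        assert np.all(props.mua == 0)
        assert not props.valid.any()

    def test_linearity_unit_concentrations(self, basis):
        shape = (4, 4)
        scene = PhantomScene(
            conc_maps={OXY: np.ones(shape), DEOXY: np.ones(shape)},
            scatter_amplitude=np.ones(shape),
            scatter_power=np.ones(shape),
            pixel_pitch=0.5,
        )
        props = scene_optical_properties(scene, basis, 731.0)
        row = basis.row(731.0)
        assert np.allclose(props.mua, row.sum(), rtol=0, atol=0)

    def test_vectorized_matches_per_pixel_loop(self, basis):
        scene = random_scene(shape=(12, 10), rng=5)
        props = scene_optical_properties(scene, basis, 691.0)
        row = basis.row(691.0)
        for i in range(12):
            for j in range(10):
                expected = sum(
                    row[k] * scene.conc_maps[name][i, j]
                    for k, name in enumerate(basis.names)
                )
                assert props.mua[i, j] == pytest.approx(expected, rel=1e-14)

    def test_unknown_wavelength(self, basis):
        with pytest.raises(KeyError):
            scene_optical_properties(random_scene(shape=(4, 4), rng=0), basis, 555.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PhantomScene(
                conc_maps={OXY: -np.ones((4, 4)), DEOXY: np.ones((4, 4))},
                scatter_amplitude=np.ones((4, 4)),
                scatter_power=np.ones((4, 4)),
                pixel_pitch=0.5,
            )

    def test_scatter_power_law(self):
        scene = homogeneous_scene(shape=(2, 2), scatter_amplitude=1.3, scatter_power=1.2)
        assert scene.musp(800.0) == pytest.approx(1.3)
        assert np.all(scene.musp(659.0) > scene.musp(851.0))


class TestRenderAcquisition:
    def test_planar_frames_identical_noise_free(self, basis):
        scene = homogeneous_scene(shape=(8, 8))
        stack = render_acquisition(scene, basis, ground_truth_protocol())
        frames = stack.triplet(659.0, 0.0)
        assert len(frames) == 3
        np.testing.assert_array_equal(frames[0].intensity, frames[1].intensity)
        np.testing.assert_array_equal(frames[1].intensity, frames[2].intensity)

    def test_default_protocol_renders_24_frames(self, basis):
        scene = random_scene(shape=(8, 8), rng=1)
        stack = render_acquisition(scene, basis, ground_truth_protocol())
        assert len(stack) == 24

    def test_frame_count_conservation(self, basis):
        scene = random_scene(shape=(8, 8), rng=2)
        for proto in (
            ground_truth_protocol(),
            snapshot_protocol(),
            ground_truth_protocol(wavelengths=(659.0, 851.0)),
        ):
            stack = render_acquisition(scene, basis, proto)
            assert len(stack) == proto.n_frames
            assert len({(f.wavelength, f.fx, f.phase) for f in stack.frames}) == len(stack)

    def test_demodulation_round_trip(self, basis):
        scene = random_scene(shape=(16, 24), rng=3)
        proto = ground_truth_protocol()
        stack = render_acquisition(scene, basis, proto)
        for wl in (659.0, 851.0):
            frames = stack.triplet(wl, 0.2)
            mac, _ = demodulate_three_phase(*(f.intensity for f in frames))
            props = scene_optical_properties(scene, basis, wl)
            rd_ac = diffuse_reflectance(props.mua, props.musp, 0.2, scene.refractive_index)
            np.testing.assert_allclose(mac, proto.gain / 2 * rd_ac, rtol=1e-6)

    def test_determinism_bit_identical(self, basis):
        scene = random_scene(shape=(8, 8), rng=4)
        proto = ground_truth_protocol(noise=NoiseModel(sigma_rel=0.02, shot=True, seed=9))
        s1 = render_acquisition(scene, basis, proto)
        s2 = render_acquisition(scene, basis, proto)
        for f1, f2 in zip(s1.frames, s2.frames):
            np.testing.assert_array_equal(f1.intensity, f2.intensity)

    def test_bad_pixel_pitch_rejected(self):
        with pytest.raises(ValueError, match="pitch"):
            homogeneous_scene(shape=(4, 4), pixel_pitch=0.0)

    def test_duplicate_frame_keys_rejected(self, basis):
        scene = homogeneous_scene(shape=(4, 4))
        stack = render_acquisition(scene, basis, snapshot_protocol())
        with pytest.raises(ValueError, match="duplicate"):
            AcquisitionStack(frames=stack.frames + [stack.frames[0]])


class TestMakeReference:
    def test_gain_cancellation(self, basis):
        proto = ground_truth_protocol()
        ref = make_reference(REFERENCE_OPTICS, proto, shape=(8, 8))
        scene = homogeneous_scene(shape=(8, 8))
        stack = render_acquisition(scene, basis, proto)
        mac_s, _ = demodulate_three_phase(*(f.intensity for f in stack.triplet(659.0, 0.2)))
        mac_r, _ = demodulate_three_phase(
            *(f.intensity for f in ref.stack.triplet(659.0, 0.2))
        )
        rd = calibrate(mac_s, mac_r, ref.rd_model[(659.0, 0.2)])
        props = scene_optical_properties(scene, basis, 659.0)
        truth = diffuse_reflectance(props.mua, props.musp, 0.2, 1.4)
        np.testing.assert_allclose(rd, truth, rtol=1e-9)

    def test_drift_scales_calibrated_reflectance(self, basis):
        proto = ground_truth_protocol()
        scene = homogeneous_scene(shape=(8, 8))
        stack = render_acquisition(scene, basis, proto)
        mac_s, _ = demodulate_three_phase(*(f.intensity for f in stack.triplet(659.0, 0.2)))
        drift = 1.25
        ref_plain = make_reference(REFERENCE_OPTICS, proto, shape=(8, 8))
        ref_drift = make_reference(REFERENCE_OPTICS, proto, shape=(8, 8), drift=drift)
        mac_p, _ = demodulate_three_phase(
            *(f.intensity for f in ref_plain.stack.triplet(659.0, 0.2))
        )
        mac_d, _ = demodulate_three_phase(
            *(f.intensity for f in ref_drift.stack.triplet(659.0, 0.2))
        )
        rd_p = calibrate(mac_s, mac_p, ref_plain.rd_model[(659.0, 0.2)])
        rd_d = calibrate(mac_s, mac_d, ref_drift.rd_model[(659.0, 0.2)])
        np.testing.assert_allclose(rd_d, rd_p / drift, rtol=1e-12)

    def test_model_reflectance_in_unit_interval(self):
        ref = make_reference(REFERENCE_OPTICS, ground_truth_protocol(), shape=(4, 4))
        for rd in ref.rd_model.values():
            assert 0 < rd < 1

    def test_missing_wavelength_rejected(self):
        optics = {659.0: (0.018, 1.2)}
        with pytest.raises(ValueError, match="missing"):
            make_reference(optics, ground_truth_protocol(), shape=(4, 4))


class TestOcclusionSeries:
    def test_zero_length_occlusion_constant(self):
        scene = homogeneous_scene(shape=(8, 8), sto2=0.7)
        timeline = OcclusionTimeline(baseline_s=30, occlusion_s=0.0, release_s=30, dt_s=10)
        series = simulate_occlusion_series(scene, timeline)
        for _, s in series:
            np.testing.assert_allclose(np.nan_to_num(s.sto2), 0.7, atol=1e-9)

    def test_initial_condition_exact(self):
        scene = homogeneous_scene(shape=(8, 8), sto2=0.65)
        series = simulate_occlusion_series(scene, OcclusionTimeline(dt_s=30))
        t0, s0 = series[0]
        assert t0 == 0.0
        np.testing.assert_allclose(np.nan_to_num(s0.sto2), 0.65, atol=1e-12)

    def test_monotone_during_occlusion(self):
        scene = random_scene(shape=(8, 8), rng=6)
        timeline = OcclusionTimeline(baseline_s=20, occlusion_s=120, release_s=40, dt_s=10)
        series = simulate_occlusion_series(scene, timeline)
        means = [
            (t, float(np.nanmean(s.sto2)))
            for t, s in series
            if timeline.baseline_s <= t <= timeline.baseline_s + timeline.occlusion_s
        ]
        values = [m for _, m in means]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_overshoot_after_release(self):
        scene = homogeneous_scene(shape=(4, 4), sto2=0.6)
        timeline = OcclusionTimeline(
            baseline_s=10, occlusion_s=60, release_s=120, dt_s=2, overshoot=0.1
        )
        series = simulate_occlusion_series(scene, timeline)
        release = [
            float(np.nanmean(s.sto2))
            for t, s in series
            if t > timeline.baseline_s + timeline.occlusion_s
        ]
        assert max(release) > 0.6 + 0.02  # transient above baseline

    def test_total_hemoglobin_conserved(self):
        scene = random_scene(shape=(8, 8), rng=7)
        hbt = scene.conc_maps[OXY] + scene.conc_maps[DEOXY]
        series = simulate_occlusion_series(scene, OcclusionTimeline(dt_s=60))
        for _, s in series:
            np.testing.assert_allclose(
                s.conc_maps[OXY] + s.conc_maps[DEOXY], hbt, rtol=1e-12
            )

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            OcclusionTimeline(occluded_sto2=1.4)

    def test_empty_region_rejected(self):
        scene = homogeneous_scene(shape=(4, 4))
        with pytest.raises(ValueError, match="empty"):
            simulate_occlusion_series(
                scene, OcclusionTimeline(), region=np.zeros((4, 4), bool)
            )
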