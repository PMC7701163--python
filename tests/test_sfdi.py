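import itertools

import numpy as np
import pytest

from oximap.chromophores import DEOXY, OXY
from oximap.diffusion import diffuse_reflectance
from oximap.phantoms import (
    AcquisitionStack,
    ground_truth_protocol,
    homogeneous_scene,
    make_reference,
    random_scene,
    render_acquisition,
    scene_optical_properties,
)
from oximap.sfdi import (
    ConcentrationMaps,
    build_lut,
    calibrate,
    compute_sto2,
    demodulate_three_phase,
    fit_chromophores,
    invert_lut,
    sfdi_ground_truth,
)
from tests.conftest import REFERENCE_OPTICS

PHASES = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


class TestDemodulation:
    def test_constant_frames(self):
        c = 4.2 * np.ones((5, 5))
        mac, mdc = demodulate_three_phase(c, c, c)
        np.testing.assert_allclose(mac, 0.0, atol=1e-12)
        np.testing.assert_allclose(mdc, 4.2)

    def test_sinusoid_identity(self):
        rng = np.random.default_rng(0)
        shape = (40, 25)
        a = rng.uniform(1, 5, shape)
        b = rng.uniform(0.1, 1, shape) * a
        theta = rng.uniform(0, 2 * np.pi, shape)
        frames = [a + b * np.cos(theta + p) for p in PHASES]
        mac, mdc = demodulate_three_phase(*frames)
        np.testing.assert_allclose(mac, b, rtol=1e-10)
        np.testing.assert_allclose(mdc, a, rtol=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            demodulate_three_phase(np.ones((2, 2)), np.ones((2, 2)), np.ones((3, 2)))


class TestCalibrate:
    def test_self_calibration(self):
        m = np.random.default_rng(1).uniform(1, 2, (4, 4))
        np.testing.assert_allclose(calibrate(m, m, 0.4), 0.4)

    def test_gain_invariance(self):
        rng = np.random.default_rng(2)
        ms, mr = rng.uniform(1, 2, (4, 4)), rng.uniform(1, 2, (4, 4))
        np.testing.assert_allclose(
            calibrate(2 * ms, 2 * mr, 0.3), calibrate(ms, mr, 0.3), rtol=1e-14
        )

    def test_zero_reference_flagged_not_raised(self):
        mr = np.ones((2, 2))
        mr[0, 0] = 0.0
        rd = calibrate(np.ones((2, 2)), mr, 0.5)
        assert np.isnan(rd[0, 0]) and np.isfinite(rd[1, 1])

    def test_bad_model_value(self):
        with pytest.raises(ValueError):
            calibrate(np.ones((2, 2)), np.ones((2, 2)), 1.5)

    def test_illumination_field_cancels_exactly(self):
        rng = np.random.default_rng(3)
        field = rng.uniform(0.5, 1.5, (6, 6))
        ms, mr = 2.0 * np.ones((6, 6)), 1.0 * np.ones((6, 6))
        np.testing.assert_array_equal(
            calibrate(field * ms, field * mr, 0.4), calibrate(ms, mr, 0.4)
        )


class TestBuildLut:
    def test_forward_evaluation_count_on_tiny_grid(self):
        calls = []

        def counting_forward(mua, musp, fx, n):
            calls.append(np.shape(mua))
            return diffuse_reflectance(mua, musp, fx, n)

        build_lut(forward=counting_forward, n_mua=2, n_musp=2)
        # one vectorized call per table, each over the full 2x2 grid
        assert calls == [(2, 2), (2, 2)]

    def test_tables_in_unit_interval(self, small_lut):
        assert np.all((small_lut.rd_dc > 0) & (small_lut.rd_dc < 1))
        assert np.all((small_lut.rd_ac > 0) & (small_lut.rd_ac < 1))

    def test_injectivity_failure_reported(self):
        def degenerate(mua, musp, fx, n):
            return np.full(np.broadcast(mua, musp).shape, 0.3 if fx else 0.5)

        with pytest.raises(ValueError, match="injective"):
            build_lut(forward=degenerate, n_mua=4, n_musp=4)


class TestInvertLut:
    def test_grid_node_identity_nearest(self, small_lut):
        ii = [5, 40, 90]
        jj = [3, 50, 88]
        rd_dc = small_lut.rd_dc[np.ix_(ii, jj)]
        rd_ac = small_lut.rd_ac[np.ix_(ii, jj)]
        props = invert_lut(rd_dc, rd_ac, small_lut, method="nearest")
        np.testing.assert_allclose(
            props.mua, np.broadcast_to(small_lut.mua_grid[ii][:, None], (3, 3)), rtol=1e-12
        )
        np.testing.assert_allclose(
            props.musp, np.broadcast_to(small_lut.musp_grid[jj][None, :], (3, 3)), rtol=1e-12
        )

    def test_homogeneous_input_gives_constant_output(self, small_lut):
        rd_dc = np.full((6, 6), 0.45)
        rd_ac = np.full((6, 6), 0.10)
        props = invert_lut(rd_dc, rd_ac, small_lut)
        assert np.ptp(props.mua) == 0 and np.ptp(props.musp) == 0

    def test_off_grid_round_trip(self, lut):
        rng = np.random.default_rng(10)
        mua = np.exp(rng.uniform(np.log(0.003), np.log(0.3), 1000))
        musp = np.exp(rng.uniform(np.log(0.3), np.log(4.0), 1000))
        rd_dc = diffuse_reflectance(mua, musp, 0.0, lut.n_index)
        rd_ac = diffuse_reflectance(mua, musp, lut.fx_ac, lut.n_index)
        props = invert_lut(rd_dc[None], rd_ac[None], lut)
        rel_mua = np.abs(props.mua[0] / mua - 1)
        rel_musp = np.abs(props.musp[0] / musp - 1)
        assert rel_mua.max() < 0.02 and rel_musp.max() < 0.02

    def test_nan_reflectance_marked_invalid(self, small_lut):
        rd_dc = np.full((2, 2), 0.45)
        rd_ac = np.full((2, 2), 0.10)
        rd_dc[0, 0] = np.nan
        props = invert_lut(rd_dc, rd_ac, small_lut)
        assert not props.valid[0, 0] and props.valid[1, 1]
        assert np.isfinite(props.mua).all()  # nearest-node fallback fill

    def test_out_of_gamut_flagged(self, small_lut):
        props = invert_lut(np.array([[0.99]]), np.array([[0.0001]]), small_lut)
        assert not props.valid[0, 0]


def _brute_force_nnls(e, mua, grid=np.linspace(0, 0.2, 401)):
    best, best_r = None, np.inf
    for c1, c2 in itertools.product(grid, grid):
        r = np.linalg.norm(e @ np.array([c1, c2]) - mua)
        if r < best_r:
            best, best_r = (c1, c2), r
    return np.array(best), best_r


class TestFitChromophores:
    def test_forward_then_fit_round_trip(self, basis):
        rng = np.random.default_rng(4)
        shape = (7, 9)
        c_oxy = rng.uniform(0.01, 0.05, shape)
        c_deoxy = rng.uniform(0.005, 0.03, shape)
        wavelengths = basis.wavelengths.tolist()
        e = basis.submatrix(wavelengths)
        mua_stack = np.einsum(
            "wn,nij->wij", e, np.stack([c_oxy, c_deoxy])[[basis.oxy_column, basis.deoxy_column]]
        )
        conc = fit_chromophores(mua_stack, basis, wavelengths=wavelengths)
        np.testing.assert_allclose(conc.c_oxy, c_oxy, rtol=1e-10)
        np.testing.assert_allclose(conc.c_deoxy, c_deoxy, rtol=1e-10)
        assert np.all(conc.residual < 1e-12)

    def test_zero_absorption_gives_zero_concentrations(self, basis):
        mua = np.zeros((4, 3, 3))
        conc = fit_chromophores(mua, basis, wavelengths=basis.wavelengths.tolist())
        assert not conc.c_oxy.any() and not conc.c_deoxy.any()
        assert not conc.residual.any()

    def test_matches_exact_linear_solve_when_nonnegative(self, basis):
        rng = np.random.default_rng(5)
        e = basis.submatrix([659.0, 851.0])
        c_true = rng.uniform(0.01, 0.05, (2, 50))
        mua = (e @ c_true).reshape(2, 5, 10)
        conc = fit_chromophores(mua, basis, wavelengths=[659.0, 851.0])
        exact = np.linalg.solve(e, mua.reshape(2, -1))
        np.testing.assert_allclose(conc.c_oxy.ravel(), exact[basis.oxy_column], atol=1e-12)
        np.testing.assert_allclose(
            conc.c_deoxy.ravel(), exact[basis.deoxy_column], atol=1e-12
        )

    def test_adversarial_case_clamped_matches_brute_force(self, basis):
        # absorption spectrum chosen so the unconstrained solve goes negative
        e = basis.submatrix([659.0, 851.0])
        mua_vec = np.array([0.001, 0.05])
        assert np.any(np.linalg.solve(e, mua_vec) < 0)
        conc = fit_chromophores(
            mua_vec.reshape(2, 1, 1), basis, wavelengths=[659.0, 851.0]
        )
        fitted = np.array([conc.c_oxy[0, 0], conc.c_deoxy[0, 0]])
        assert np.all(fitted >= 0) and conc.residual[0, 0] > 0
        brute, brute_r = _brute_force_nnls(e, mua_vec)
        brute_named = np.array([brute[basis.oxy_column], brute[basis.deoxy_column]])
        np.testing.assert_allclose(fitted, brute_named, atol=1e-3)
        assert conc.residual[0, 0] <= brute_r + 1e-9

    def test_rank_deficient_rejected(self, basis):
        with pytest.raises(ValueError):
            fit_chromophores(np.zeros((2, 2, 2)), basis, wavelengths=[659.0, 659.0])

    def test_single_wavelength_rejected(self, basis):
        with pytest.raises(ValueError, match="two wavelengths"):
            fit_chromophores(np.zeros((1, 2, 2)), basis, wavelengths=[659.0])


class TestComputeSto2:
    def test_symmetry(self):
        c = ConcentrationMaps(np.full((2, 2), 0.3), np.full((2, 2), 0.3), np.zeros((2, 2)))
        out = compute_sto2(c)
        np.testing.assert_allclose(out.sto2, 0.5)
        assert out.valid.all()

    def test_boundary(self):
        c = ConcentrationMaps(np.full((2, 2), 0.3), np.zeros((2, 2)), np.zeros((2, 2)))
        np.testing.assert_allclose(compute_sto2(c).sto2, 1.0)

    def test_below_threshold_invalid(self):
        c = ConcentrationMaps(
            np.full((2, 2), 1e-9), np.full((2, 2), 1e-9), np.zeros((2, 2))
        )
        out = compute_sto2(c, min_total=1e-6)
        assert not out.valid.any()


class TestGroundTruthPipeline:
    def test_noise_free_recovery(self, basis, lut):
        from oximap.metrics import nmae
        from oximap.sfdi import StO2Map

        scene = random_scene(shape=(24, 24), rng=20)
        proto = ground_truth_protocol()
        ref = make_reference(REFERENCE_OPTICS, proto, shape=(24, 24))
        stack = render_acquisition(scene, basis, proto)
        sto2 = sfdi_ground_truth(stack, ref, lut, basis)
        truth = StO2Map(np.nan_to_num(scene.sto2), scene.mask)
        assert nmae(sto2, truth).nmae < 0.005

    def test_homogeneous_scene_uniform_output(self, basis, lut):
        scene = homogeneous_scene(shape=(16, 16), sto2=0.7)
        proto = ground_truth_protocol()
        ref = make_reference(REFERENCE_OPTICS, proto, shape=(16, 16))
        stack = render_acquisition(scene, basis, proto)
        sto2 = sfdi_ground_truth(stack, ref, lut, basis)
        assert np.ptp(sto2.sto2) < 1e-6
        assert abs(float(sto2.sto2.mean()) - 0.7) < 0.005

    def test_frame_order_invariance(self, basis, lut):
        scene = random_scene(shape=(12, 12), rng=21)
        proto = ground_truth_protocol()
        ref = make_reference(REFERENCE_OPTICS, proto, shape=(12, 12))
        stack = render_acquisition(scene, basis, proto)
        shuffled = AcquisitionStack(
            frames=[stack.frames[i] for i in np.random.default_rng(0).permutation(24)],
            provenance=stack.provenance,
        )
        out1 = sfdi_ground_truth(stack, ref, lut, basis)
        out2 = sfdi_ground_truth(shuffled, ref, lut, basis)
        np.testing.assert_array_equal(out1.sto2, out2.sto2)

    def test_missing_frames_reported(self, basis, lut):
        scene = random_scene(shape=(8, 8), rng=22)
        proto = ground_truth_protocol()
        ref = make_reference(REFERENCE_OPTICS, proto, shape=(8, 8))
        stack = render_acquisition(scene, basis, proto)
        partial = AcquisitionStack(frames=stack.frames[:-2], provenance=stack.provenance)
        with pytest.raises(ValueError, match="missing"):
            sfdi_ground_truth(partial, ref, lut, basis)
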