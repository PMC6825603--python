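"""Pupil modes, focal fields, null tracking and depth aberrations."""

import numpy as np
import pytest

from aostedfcs import optics as O


class TestZernike:
    def test_piston_is_constant_one(self, grid64):
        z = O.zernike_phase(1, grid64)
        assert np.allclose(z.values[grid64.mask], 1.0)

    def test_defocus_value_at_pupil_edge(self):
        # Z4 = sqrt(3)·(2ρ²−1) -> sqrt(3) at ρ=1
        grid = O.PupilGrid(256)
        z = O.zernike_phase(4, grid)
        edge = np.abs(grid.rho - 1.0) < 2.0 / 256
        on_axis = grid.rho < 0.02
        assert np.allclose(z.values[edge & grid.mask].max(), np.sqrt(3), atol=0.02)
        assert np.allclose(z.values[on_axis].mean(), -np.sqrt(3), atol=0.02)

    def test_noll_orthonormality(self):
        """Disk-averaged <Zj·Zk> is the identity for j,k in 2..22."""
        grid = O.PupilGrid(256)
        js = range(2, 23)
        Z = np.stack([O.zernike_phase(j, grid).values[grid.mask] for j in js])
        gram = Z @ Z.T / grid.mask.sum()
        assert np.abs(gram - np.eye(len(list(js)))).max() < 0.02

    def test_invalid_index_rejected(self, grid64):
        with pytest.raises(ValueError):
            O.zernike_phase(0, grid64)


class TestHighNADefocus:
    def test_zero_amplitude_gives_zero_map(self, sted_cfg, grid64):
        assert np.all(O.high_na_defocus_phase(0.0, sted_cfg, grid64).values == 0)

    def test_unscaled_profile_shape(self, sted_cfg):
        # sqrt(1-(NA·ρ/n)²): 1 at centre, ~0.3864 at the pupil edge
        grid = O.PupilGrid(256)
        pm = O.high_na_defocus_phase(1.0, sted_cfg, grid, scaled=False)
        centre = grid.rho < 0.02
        edge = (np.abs(grid.rho - 1.0) < 2.0 / 256) & grid.mask
        assert pm.values[centre].mean() == pytest.approx(1.0, abs=1e-3)
        expected_edge = np.sqrt(1 - (1.4 / 1.518) ** 2)
        assert pm.values[edge].min() == pytest.approx(expected_edge, abs=0.01)

    def test_amplitude_unit_is_339nm_of_refocus(self, sted_cfg, grid64):
        pm = O.high_na_defocus_phase(1.0, sted_cfg, grid64)
        scale = O.hnd_amplitude_scale(sted_cfg)
        # phase at pupil centre equals the scale (profile = 1 there)
        centre = grid64.rho < 0.05
        assert pm.values[centre].mean() == pytest.approx(scale, rel=1e-3)
        assert scale == pytest.approx(2 * np.pi * 1.518 * 339.0 / 755.0, rel=1e-12)


class TestZStedMask:
    def test_equal_area_default_radius(self, grid64):
        assert O.EQUAL_AREA_STEP_RADIUS == pytest.approx(1 / np.sqrt(2))
        pm = O.zsted_mask(grid64)
        inner = grid64.rho < 0.5
        assert np.allclose(pm.values[inner], np.pi)

    def test_pupil_integral_cancels(self):
        grid = O.PupilGrid(512)
        pm = O.zsted_mask(grid)
        integral = np.exp(1j * pm.values)[grid.mask].sum() / grid.mask.sum()
        assert abs(integral) < 5e-3

    def test_out_of_range_radius(self, grid64):
        with pytest.raises(ValueError):
            O.zsted_mask(grid64, step_radius=1.2)


class TestFocalIntensity:
    def test_flat_pupil_peak_at_origin_and_symmetry(self, grid64, sted_cfg, roi_small):
        flat = O.PhaseMap(np.zeros((64, 64)), grid64.mask)
        psf = O.focal_intensity(flat, sted_cfg, roi_small)
        nz, ny, nx = psf.intensity.shape
        assert np.unravel_index(np.argmax(psf.intensity), psf.intensity.shape) \
            == (nz // 2, ny // 2, nx // 2)
        assert np.allclose(psf.intensity, psf.intensity[:, :, ::-1], atol=1e-9)
        assert np.allclose(psf.intensity, psf.intensity[:, ::-1, :], atol=1e-9)
        assert np.allclose(psf.intensity, psf.intensity[::-1, :, :], atol=1e-6)

    def test_zsted_central_null(self, zsted_psf):
        nz, ny, nx = zsted_psf.intensity.shape
        assert zsted_psf.intensity[nz // 2, ny // 2, nx // 2] < 1e-3

    def test_null_fill_rises_with_defocus_mismatch_mix(self, sted_cfg, grid64,
                                                       roi_small, zsted_psf):
        """A mixed asymmetric aberration raises the tracked null intensity."""
        state = O.AberrationState({"noll:7": 0.6, "noll:5": 0.4})
        pupil = O.compose_pupil(O.zsted_mask(grid64), state, sted_cfg, grid64)
        psf = O.focal_intensity(pupil, sted_cfg, roi_small)
        from scipy.ndimage import gaussian_filter
        from aostedfcs.optics import _descend
        nz, ny, nx = psf.intensity.shape
        idx0 = _descend(gaussian_filter(zsted_psf.intensity, 1.0),
                        (nz // 2, ny // 2, nx // 2), "min")
        idx1 = _descend(gaussian_filter(psf.intensity, 1.0), idx0, "min")
        assert psf.intensity[idx1] > zsted_psf.intensity[idx0]

    def test_aberrated_peak_is_dimmer(self, sted_cfg, grid64, roi_small, zsted_psf):
        """Raw focal peak intensity drops under aberration (fixed pupil power)."""
        state = O.AberrationState({"noll:11": 1.0})
        pupil = O.compose_pupil(O.zsted_mask(grid64), state, sted_cfg, grid64)
        psf = O.focal_intensity(pupil, sted_cfg, roi_small)
        assert psf.meta["peak_intensity"] < zsted_psf.meta["peak_intensity"]


@pytest.fixture(scope="module")
def shift_setup(sted_cfg):
    grid = O.PupilGrid(192)
    roi = O.FocalROI((1600.0, 800.0, 1600.0), (10.0, 10.0, 20.0))
    mask = O.zsted_mask(grid)
    ref = O.focal_intensity(mask, sted_cfg, roi)
    return grid, roi, mask, ref


class TestPatternShift:

    def test_identical_inputs_give_zero(self, shift_setup):
        *_, ref = shift_setup
        assert O.pattern_min_shift(ref, ref) == (0.0, 0.0, 0.0)

    def test_tip_shift_matches_lambda_over_pi_na(self, sted_cfg, shift_setup):
        grid, roi, mask, ref = shift_setup
        pupil = O.compose_pupil(mask, O.AberrationState({"tip": 1.0}),
                                sted_cfg, grid)
        psf = O.focal_intensity(pupil, sted_cfg, roi)
        dx, dy, dz = O.pattern_min_shift(psf, ref, refine_radius=8)
        expected = 755.0 / (np.pi * 1.4)
        assert abs(dx) == pytest.approx(expected, abs=3.0)
        assert abs(dy) < 3.0 and abs(dz) < 5.0

    def test_shift_linearity_in_amplitude(self, sted_cfg, shift_setup):
        grid, roi, mask, ref = shift_setup
        amps = [0.5, 1.0]
        shifts = []
        for a in amps:
            pupil = O.compose_pupil(mask, O.AberrationState({"tilt": a}),
                                    sted_cfg, grid)
            psf = O.focal_intensity(pupil, sted_cfg, roi)
            shifts.append(O.pattern_min_shift(psf, ref, refine_radius=8)[1])
        slope = (np.array(amps) @ np.array(shifts)) / (np.array(amps) @ np.array(amps))
        for a, s in zip(amps, shifts):
            assert s == pytest.approx(slope * a, rel=0.02)

    def test_hnd_defocus_axial_shift_calibration(self, sted_cfg, shift_setup):
        grid, roi, mask, ref = shift_setup
        pupil = O.compose_pupil(mask, O.AberrationState({"hnd_defocus": 1.0}),
                                sted_cfg, grid)
        psf = O.focal_intensity(pupil, sted_cfg, roi)
        dx, dy, dz = O.pattern_min_shift(psf, ref)
        assert abs(dz) == pytest.approx(O.DEFOCUS_SHIFT_NM_PER_RAD, abs=4.0)


class TestDepthAberration:
    def test_matched_index_gives_zero(self):
        cfg = O.OpticalConfig(n_sample=1.518)
        st = O.depth_aberration(3.0, cfg)
        assert all(abs(v) < 1e-12 for v in st.modes.values())

    def test_linear_in_depth(self):
        cfg = O.OpticalConfig(n_sample=1.398)
        c3 = O.depth_aberration(3.0, cfg).amplitude("noll:11")
        c6 = O.depth_aberration(6.0, cfg).amplitude("noll:11")
        assert c6 == pytest.approx(2.0 * c3, rel=1e-9)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            O.depth_aberration(-1.0, O.OpticalConfig())

    def test_secondary_spherical_also_returned(self):
        cfg = O.OpticalConfig(n_sample=1.398)
        st = O.depth_aberration(3.0, cfg)
        assert set(st.modes) == {"noll:11", "noll:22"}
        assert st.amplitude("noll:22") != 0.0


class TestComposeAndState:
    def test_empty_state_leaves_base(self, sted_cfg, grid64):
        base = O.zsted_mask(grid64)
        out = O.compose_pupil(base, O.AberrationState(), sted_cfg, grid64)
        assert np.array_equal(out.values, base.values)

    def test_composition_is_additive_and_cancels(self, sted_cfg, grid64):
        base = O.zsted_mask(grid64)
        st = O.AberrationState({"noll:11": 0.5})
        twice = O.compose_pupil(
            O.compose_pupil(base, O.AberrationState({"noll:11": 0.25}),
                            sted_cfg, grid64),
            O.AberrationState({"noll:11": 0.25}), sted_cfg, grid64)
        once = O.compose_pupil(base, st, sted_cfg, grid64)
        assert np.allclose(twice.values, once.values, atol=1e-12)
        undo = O.compose_pupil(once, -st, sted_cfg, grid64)
        assert np.allclose(undo.values, base.values, atol=1e-12)

    def test_unknown_mode_rejected(self, sted_cfg, grid64):
        with pytest.raises(KeyError):
            O.compose_pupil(O.zsted_mask(grid64),
                            O.AberrationState({"weird": 1.0}), sted_cfg, grid64)

    def test_tip_tilt_canonicalization(self):
        st = O.AberrationState({"noll:2": 0.3, "tilt": -0.2})
        assert st.amplitude("tip") == 0.3
        assert st.amplitude("noll:3") == -0.2


def test_psf_tiff_roundtrip(tmp_path, zsted_psf):
    path = tmp_path / "psf.tif"
    O.psf_to_tiff(zsted_psf, path)
    back = O.psf_from_tiff(path)
    assert back.intensity.shape == zsted_psf.intensity.shape
    assert np.allclose(back.intensity, zsted_psf.intensity, atol=1e-6)
    assert back.voxel == zsted_psf.voxel
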