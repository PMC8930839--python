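"""Preprocessing: masks, nuisance regression, filtering, smoothing."""

import numpy as np
import pytest
from scipy import ndimage

from gwfcc import preprocess as pp
from gwfcc.errors import EmptyMaskError, ShapeError

from conftest import make_record


def mask(data, tissue="GM", source="group"):
    return pp.TissueMask(data=np.asarray(data, bool), tissue=tissue, source=source)


def signals(ts, tr=2.5, grid=(4, 4, 4), band=None, indices=None):
    ts = np.asarray(ts, float)
    if indices is None:
        indices = np.arange(ts.shape[1])
    return pp.TissueSignalSet(
        voxel_indices=indices, timeseries=ts, tissue="GM", tr_s=tr,
        grid_dims=grid, band_hz=band,
    )


# ---------------------------------------------------------------- volume drop

class TestDropInitialVolumes:
    def test_drops_bold_and_motion_from_front(self, rng):
        rec = make_record(rng.normal(size=(4, 4, 4, 139)),
                          motion=rng.normal(size=(139, 6)))
        out = pp.drop_initial_volumes(rec, 10)
        assert out.n_timepoints == 129
        np.testing.assert_array_equal(out.bold, rec.bold[..., 10:])
        np.testing.assert_array_equal(out.motion, rec.motion[10:])
        np.testing.assert_array_equal(out.affine, rec.affine)

    def test_zero_drop_is_identity(self, rng):
        rec = make_record(rng.normal(size=(4, 4, 4, 20)))
        assert pp.drop_initial_volumes(rec, 0) is rec

    def test_dropping_everything_is_an_error(self, rng):
        rec = make_record(rng.normal(size=(4, 4, 4, 20)))
        with pytest.raises(ValueError):
            pp.drop_initial_volumes(rec, 20)


# ------------------------------------------------------------------- masking

class TestIndividualMasks:
    def test_argmax_assignment_and_background(self, rng):
        probs = {
            "GM": np.array([[[0.7, 0.05]]]),
            "WM": np.array([[[0.2, 0.05]]]),
            "CSF": np.array([[[0.1, 0.05]]]),
        }
        rec = make_record(rng.normal(size=(1, 1, 2, 5)), probs=probs)
        gm, wm, csf = pp.build_individual_masks(rec)
        assert gm.data[0, 0, 0] and not wm.data[0, 0, 0] and not csf.data[0, 0, 0]
        assert not (gm.data[0, 0, 1] or wm.data[0, 0, 1] or csf.data[0, 0, 1])

    @pytest.mark.parametrize(
        "p, winner",
        [
            ((0.5, 0.5, 0.0), "GM"),   # GM beats WM on ties
            ((0.0, 0.5, 0.5), "WM"),   # WM beats CSF
            ((0.5, 0.0, 0.5), "GM"),   # GM beats CSF
            ((0.33, 0.33, 0.33), "GM"),  # three-way tie -> first in precedence
        ],
    )
    def test_tie_break_precedence_gm_wm_csf(self, p, winner, rng):
        probs = {t: np.full((1, 1, 1), v)
                 for t, v in zip(("GM", "WM", "CSF"), p)}
        rec = make_record(rng.normal(size=(1, 1, 1, 5)), probs=probs)
        masks = {m.tissue: m for m in pp.build_individual_masks(rec)}
        assert masks[winner].data.all()
        for t, m in masks.items():
            if t != winner:
                assert not m.data.any()


class TestGroupMask:
    def make_stack(self, present_counts, n_subjects=5):
        """One 1D grid voxel per entry; entry = number of subjects containing it."""
        masks = []
        for s in range(n_subjects):
            data = np.array([s < c for c in present_counts]).reshape(-1, 1, 1)
            masks.append(mask(data, source="individual"))
        return masks

    def test_strictly_greater_than_threshold(self):
        group = pp.build_group_mask(self.make_stack([4, 3, 5, 0]), "GM")
        np.testing.assert_array_equal(
            group.data.ravel(), [True, False, True, False]
        )  # 0.8 > 0.6 in, 0.6 out (strict), 1.0 in
        np.testing.assert_allclose(group.occupancy.ravel(), [0.8, 0.6, 1.0, 0.0])

    def test_all_empty_gives_empty_mask(self):
        group = pp.build_group_mask(self.make_stack([0, 0]), "GM")
        assert group.n_voxels == 0

    def test_mixed_grids_rejected(self):
        a = mask(np.ones((2, 2, 2)), source="individual")
        b = mask(np.ones((3, 2, 2)), source="individual")
        with pytest.raises(ShapeError):
            pp.build_group_mask([a, b], "GM")


class TestBoundaryExclusion:
    @staticmethod
    def brute_force(gm, wm):
        """Oracle: remove overlap, then scan all 6-neighbour pairs."""
        gm1 = gm & ~(gm & wm)
        wm1 = wm & ~(gm & wm)
        gm2, wm2 = gm1.copy(), wm1.copy()
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        nx, ny, nz = gm.shape
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    for dx, dy, dz in offsets:
                        n = (x + dx, y + dy, z + dz)
                        if not all(0 <= c < s for c, s in zip(n, gm.shape)):
                            continue
                        if gm1[x, y, z] and wm1[n]:
                            gm2[x, y, z] = False
                        if wm1[x, y, z] and gm1[n]:
                            wm2[x, y, z] = False
        return gm2, wm2

    def test_touching_slabs_lose_contact_layer(self):
        gm = np.zeros((6, 4, 4), bool)
        wm = np.zeros((6, 4, 4), bool)
        gm[0:2] = True   # slab x in {0,1}
        wm[2:4] = True   # slab x in {2,3}: contact at x=1|2
        got_gm, got_wm = pp.exclude_boundary_and_mixed(mask(gm), mask(wm, "WM"))
        exp_gm, exp_wm = self.brute_force(gm, wm)
        np.testing.assert_array_equal(got_gm.data, exp_gm)
        np.testing.assert_array_equal(got_wm.data, exp_wm)
        assert not got_gm.data[1].any() and not got_wm.data[2].any()

    def test_separated_masks_unchanged(self):
        gm = np.zeros((8, 4, 4), bool)
        wm = np.zeros((8, 4, 4), bool)
        gm[0:2] = True
        wm[4:6] = True
        got_gm, got_wm = pp.exclude_boundary_and_mixed(mask(gm), mask(wm, "WM"))
        np.testing.assert_array_equal(got_gm.data, gm)
        np.testing.assert_array_equal(got_wm.data, wm)

    def test_identical_masks_become_empty(self):
        m = np.ones((3, 3, 3), bool)
        got_gm, got_wm = pp.exclude_boundary_and_mixed(mask(m), mask(m, "WM"))
        assert got_gm.n_voxels == 0 and got_wm.n_voxels == 0

    def test_random_masks_match_brute_force_and_invariant(self, rng):
        gm = rng.random((7, 6, 5)) < 0.35
        wm = rng.random((7, 6, 5)) < 0.35
        got_gm, got_wm = pp.exclude_boundary_and_mixed(mask(gm), mask(wm, "WM"))
        exp_gm, exp_wm = self.brute_force(gm, wm)
        np.testing.assert_array_equal(got_gm.data, exp_gm)
        np.testing.assert_array_equal(got_wm.data, exp_wm)
        # disjoint and non-adjacent by scan
        assert not (got_gm.data & got_wm.data).any()
        six = ndimage.generate_binary_structure(3, 1)
        assert not (ndimage.binary_dilation(got_gm.data, six) & got_wm.data).any()


# ---------------------------------------------------------------- extraction

class TestExtractSignals:
    def test_columns_match_voxels_in_linear_order(self, rng):
        bold = rng.normal(size=(3, 3, 3, 10))
        rec = make_record(bold)
        m = np.zeros((3, 3, 3), bool)
        m[0, 1, 2] = m[2, 0, 1] = True
        out = pp.extract_tissue_signals(rec, mask(m))
        # oracle: naive per-voxel loop in increasing linear-index order
        expected = np.array(
            [bold[idx] for idx in zip(*np.unravel_index(
                np.flatnonzero(m.ravel()), m.shape))]
        ).T
        np.testing.assert_array_equal(out.timeseries, expected)
        assert np.all(np.diff(out.voxel_indices) > 0)

    def test_full_grid_mask(self, rng):
        rec = make_record(rng.normal(size=(2, 2, 2, 4)))
        out = pp.extract_tissue_signals(rec, mask(np.ones((2, 2, 2))))
        assert out.timeseries.shape == (4, 8)

    def test_empty_mask_raises(self, rng):
        rec = make_record(rng.normal(size=(2, 2, 2, 4)))
        with pytest.raises(EmptyMaskError):
            pp.extract_tissue_signals(rec, mask(np.zeros((2, 2, 2))))


# ---------------------------------------------------------------- regression

class TestFriston24:
    def test_matches_hand_written_loop(self, rng):
        motion = rng.normal(size=(9, 6))
        got = pp.expand_friston24(motion)
        exp = np.zeros((9, 24))
        for t in range(9):
            for j in range(6):
                exp[t, j] = motion[t, j]
                exp[t, 6 + j] = motion[t - 1, j] if t > 0 else 0.0
                exp[t, 12 + j] = motion[t, j] ** 2
                exp[t, 18 + j] = motion[t - 1, j] ** 2 if t > 0 else 0.0
        np.testing.assert_allclose(got, exp)

    def test_constant_motion(self):
        motion = np.full((5, 6), 3.0)
        got = pp.expand_friston24(motion)
        assert np.all(got[:, :6] == 3.0)
        assert np.all(got[:, 12:18] == 9.0)
        assert np.all(got[0, 6:12] == 0.0) and np.all(got[1:, 6:12] == 3.0)

    def test_zero_motion_and_bad_shape(self):
        assert not pp.expand_friston24(np.zeros((4, 6))).any()
        with pytest.raises(ShapeError):
            pp.expand_friston24(np.zeros((4, 5)))


class TestRegressNuisance:
    def make_design(self, rng, n_t=30):
        motion = np.cumsum(rng.normal(scale=0.1, size=(n_t, 6)), axis=0)
        csf = rng.normal(size=n_t)
        return pp.build_nuisance_design(motion, csf)

    def test_design_is_27_columns_with_intercept(self, rng):
        design = self.make_design(rng)
        assert design.columns.shape[1] == 27
        assert design.column_names[0] == "intercept"
        np.testing.assert_array_equal(design.columns[:, 0], 1.0)

    def test_perfect_fit_of_csf_regressor(self, rng):
        design = self.make_design(rng)
        csf = design.columns[:, design.column_names.index("csf_mean")]
        out = pp.regress_nuisance(signals(csf[:, None], grid=(30, 1, 1)), design)
        np.testing.assert_allclose(out.timeseries, 0.0, atol=1e-10)

    def test_intercept_only_demeans(self):
        design = pp.NuisanceDesign(columns=np.ones((10, 1)),
                                   column_names=["intercept"])
        y = np.arange(10.0)[:, None]
        out = pp.regress_nuisance(signals(y, grid=(10, 1, 1)), design)
        np.testing.assert_allclose(out.timeseries, y - y.mean(), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        design = self.make_design(rng)
        y = rng.normal(size=(30, 7))
        out = pp.regress_nuisance(signals(y, grid=(30, 1, 1)), design)
        X = design.columns
        resid = y - X @ np.linalg.pinv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(out.timeseries, resid, atol=1e-8)
        # residuals orthogonal to the design, zero mean (intercept present)
        rel = np.abs(X.T @ out.timeseries).max() / np.abs(y).max()
        assert rel < 1e-8
        np.testing.assert_allclose(out.timeseries.mean(axis=0), 0.0, atol=1e-10)

    def test_zero_motion_columns_are_pruned(self, rng):
        design = pp.build_nuisance_design(np.zeros((20, 6)), rng.normal(size=20))
        y = rng.normal(size=(20, 3))
        out = pp.regress_nuisance(signals(y, grid=(20, 1, 1)), design)
        assert out.timeseries.shape == y.shape

    def test_rank_deficient_design_names_columns(self, rng):
        motion = np.cumsum(rng.normal(size=(20, 6)), axis=0)
        motion[:, 1] = motion[:, 0]  # duplicated parameter -> collinear Friston block
        design = pp.build_nuisance_design(motion, rng.normal(size=20))
        with pytest.raises(np.linalg.LinAlgError, match="friston24"):
            pp.regress_nuisance(signals(rng.normal(size=(20, 2)), grid=(20, 1, 1)),
                                design)


# ----------------------------------------------------------------- filtering

class TestBandpass:
    def test_exact_bin_sinusoid_passes(self):
        # sinusoid on an exact rFFT bin inside the GM band
        t = np.arange(100)
        k = 13  # f = 13 / (100 * 2.5) = 0.052 Hz
        x = np.sin(2 * np.pi * k * t / 100)
        out = pp.bandpass_filter(signals(x[:, None], grid=(100, 1, 1)), 0.01, 0.1)
        err = np.linalg.norm(out.timeseries[:, 0] - x) / np.linalg.norm(x)
        assert err < 1e-8
        assert out.band_hz == (0.01, 0.1)

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(100)
        k = 45  # f = 0.18 Hz, above the 0.1 Hz GM cut
        x = np.sin(2 * np.pi * k * t / 100)
        out = pp.bandpass_filter(signals(x[:, None], grid=(100, 1, 1)), 0.01, 0.1)
        assert np.abs(out.timeseries).max() < 1e-10 * np.abs(x).max() + 1e-12

    def test_white_noise_matches_direct_dft_oracle(self, rng):
        x = rng.normal(size=(64, 5))
        out = pp.bandpass_filter(signals(x, grid=(64, 1, 1)), 0.01, 0.1)
        # O(T^2) direct-summation DFT oracle
        T = 64
        n = np.arange(T)
        for col in range(5):
            F = np.array([np.sum(x[:, col] * np.exp(-2j * np.pi * k * n / T))
                          for k in range(T)])
            freqs = np.fft.fftfreq(T, d=2.5)
            keep = (np.abs(freqs) >= 0.01) & (np.abs(freqs) <= 0.1)
            F[~keep] = 0
            expected = np.real(np.array(
                [np.sum(F * np.exp(2j * np.pi * k * n / T)) for k in range(T)]
            )) / T
            np.testing.assert_allclose(out.timeseries[:, col], expected, atol=1e-8)
        # no spectral mass outside the band
        spec = np.abs(np.fft.rfft(out.timeseries, axis=0))
        freqs = np.fft.rfftfreq(T, d=2.5)
        outside = (freqs < 0.01) | (freqs > 0.1)
        assert spec[outside].max() < 1e-10

    def test_filtered_series_are_real(self, rng):
        x = rng.normal(size=(50, 3))
        out = pp.bandpass_filter(signals(x, grid=(50, 1, 1)), 0.01, 0.15)
        assert np.isrealobj(out.timeseries)

    def test_band_above_nyquist_rejected(self, rng):
        x = rng.normal(size=(50, 1))
        with pytest.raises(ValueError):
            pp.bandpass_filter(signals(x, grid=(50, 1, 1)), 0.01, 0.25)


# ----------------------------------------------------------------- smoothing

def direct_gaussian_smooth(data, m, sigma_vox, truncate=4.0):
    """Triple-loop masked convolution oracle with the sampled, truncated kernel."""
    radius = int(truncate * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma_vox) ** 2)
    k1 /= k1.sum()
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    num = np.zeros_like(data, dtype=float)
    den = np.zeros(data.shape, dtype=float)
    nx, ny, nz = data.shape
    masked = np.where(m, data, 0.0)
    for x0 in range(nx):
        for y0 in range(ny):
            for z0 in range(nz):
                acc_n = acc_d = 0.0
                for dx in range(-radius, radius + 1):
                    for dy in range(-radius, radius + 1):
                        for dz in range(-radius, radius + 1):
                            p = (x0 + dx, y0 + dy, z0 + dz)
                            if not all(0 <= c < s for c, s in zip(p, data.shape)):
                                continue
                            w = kernel[dx + radius, dy + radius, dz + radius]
                            acc_n += w * masked[p]
                            acc_d += w * m[p]
                num[x0, y0, z0] = acc_n
                den[x0, y0, z0] = acc_d
    with np.errstate(invalid="ignore"):
        out = num / den
    return np.where(m, out, 0.0)


class TestSmoothing:
    def test_fwhm_zero_is_identity_inside_mask(self, rng):
        data = rng.normal(size=(5, 5, 5))
        m = mask(rng.random((5, 5, 5)) < 0.7)
        out = pp.smooth_volumes(data, 0.0, m, voxel_size_mm=4.0)
        np.testing.assert_array_equal(out[m.data], data[m.data])
        assert np.all(out[~m.data] == 0)

    def test_constants_preserved_by_mask_renormalization(self, rng):
        m = mask(rng.random((6, 6, 6)) < 0.5)
        data = np.full((6, 6, 6), 3.25)
        out = pp.smooth_volumes(data, 4.0, m, voxel_size_mm=4.0)
        np.testing.assert_allclose(out[m.data], 3.25, atol=1e-12)

    def test_delta_matches_triple_loop_oracle(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 1.0
        m = mask(np.ones((8, 8, 8)))
        fwhm, voxel = 4.0, 4.0
        out = pp.smooth_volumes(data, fwhm, m, voxel_size_mm=voxel)
        sigma = fwhm / (voxel * pp.FWHM_PER_SIGMA)
        exp = direct_gaussian_smooth(data, m.data, sigma)
        np.testing.assert_allclose(out, exp, atol=1e-8)

    def test_random_masked_field_matches_oracle(self, rng):
        data = rng.normal(size=(8, 8, 8))
        m = mask(rng.random((8, 8, 8)) < 0.6)
        out = pp.smooth_volumes(data, 6.0, m, voxel_size_mm=4.0)
        sigma = 6.0 / (4.0 * pp.FWHM_PER_SIGMA)
        exp = direct_gaussian_smooth(data, m.data, sigma)
        np.testing.assert_allclose(out, exp, atol=1e-8)

    def test_no_leak_from_outside_mask(self, rng):
        data = rng.normal(size=(6, 6, 6))
        m = np.zeros((6, 6, 6), bool)
        m[1:4, 1:4, 1:4] = True
        contaminated = data.copy()
        contaminated[~m] = 1e9
        a = pp.smooth_volumes(data, 4.0, mask(m), voxel_size_mm=4.0)
        b = pp.smooth_volumes(contaminated, 4.0, mask(m), voxel_size_mm=4.0)
        np.testing.assert_allclose(a[m], b[m], rtol=1e-12)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            pp.smooth_volumes(np.zeros((3, 3, 3)), -1.0,
                              mask(np.ones((3, 3, 3))), voxel_size_mm=4.0)

    def test_4d_series_smoothed_per_volume(self, rng):
        data = rng.normal(size=(6, 6, 6, 3))
        m = mask(rng.random((6, 6, 6)) < 0.6)
        out = pp.smooth_volumes(data, 4.0, m, voxel_size_mm=4.0)
        for t in range(3):
            single = pp.smooth_volumes(data[..., t], 4.0, m, voxel_size_mm=4.0)
            np.testing.assert_allclose(out[..., t], single, atol=1e-10)
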