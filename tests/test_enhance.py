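"""AGSW guided filter: oracle equivalences and invariants."""

import numpy as np
import pytest

from btc.enhance import (
    SIDE_WINDOWS,
    AGSWParams,
    StructuringElement,
    agsw_filter,
    agsw_weight_bank,
    aggregate_coeffs,
    apply_guided_filter,
    compute_gradient_guidance,
    fit_window_coeffs,
    morphological_cleanup,
    select_side_window,
)
from btc.phantom import PhantomSpec, generate_phantom


def brute_force_coeffs(p_win, y_win, w_win, eps, loss_form="standard"):
    """Independent oracle: solve the 2-parameter weighted normal
    equations (with ridge on the gain) as a dense linear system."""
    y = y_win.ravel()
    if loss_form == "literal":
        y = y + 1.0  # the shifted-guidance residual a*(Y+1) + b - p
    p = p_win.ravel()
    w = w_win.ravel()
    A = np.array([
        [np.sum(w * y * y) + eps, np.sum(w * y)],
        [np.sum(w * y), np.sum(w)],
    ])
    rhs = np.array([np.sum(w * y * p), np.sum(w * p)])
    a, b = np.linalg.solve(A, rhs)
    return a, b


class TestGuidance:
    def test_constant_image_passes_through(self):
        img = np.full((8, 8), 0.4)
        assert np.array_equal(compute_gradient_guidance(img).pixels, img)

    def test_step_edge_gradient_peaks_on_step(self):
        img = np.where(np.arange(16)[None, :] >= 8, 1.0, 0.0) * np.ones((16, 16))
        from btc.enhance import gradient_magnitude

        g = gradient_magnitude(img)
        assert set(np.argmax(g, axis=1)) <= {7, 8}

    def test_matches_finite_difference_recomputation(self, rng):
        """Direct stencil oracle: central differences in the interior,
        one-sided differences on the borders."""
        img = rng.random((16, 16))
        gr = np.empty_like(img)
        gc = np.empty_like(img)
        gr[1:-1, :] = (img[2:, :] - img[:-2, :]) / 2.0
        gr[0, :] = img[1, :] - img[0, :]
        gr[-1, :] = img[-1, :] - img[-2, :]
        gc[:, 1:-1] = (img[:, 2:] - img[:, :-2]) / 2.0
        gc[:, 0] = img[:, 1] - img[:, 0]
        gc[:, -1] = img[:, -1] - img[:, -2]
        expected = np.hypot(gr, gc)
        from btc.enhance import gradient_magnitude

        assert np.allclose(gradient_magnitude(img), expected, atol=1e-12)


class TestWeightBank:
    def test_isotropic_full_window_symmetry(self):
        params = AGSWParams(sigma_major=1.5, sigma_minor=1.5)
        mask = agsw_weight_bank(params)[(0.0, "full")]
        assert np.allclose(mask, np.rot90(mask), atol=1e-15)

    def test_nonnegative_unit_sum(self):
        bank = agsw_weight_bank(AGSWParams())
        for mask in bank.values():
            assert (mask >= 0).all()
            assert abs(mask.sum() - 1.0) < 1e-12

    def test_side_window_support(self):
        params = AGSWParams()
        bank = agsw_weight_bank(params)
        r = params.radius
        assert np.all(bank[(0.0, "left")][:, r + 1 :] == 0)
        assert np.all(bank[(45.0, "up")][r + 1 :, :] == 0)
        nw = bank[(90.0, "nw")]
        assert np.all(nw[r + 1 :, :] == 0) and np.all(nw[:, r + 1 :] == 0)


class TestFitWindowCoeffs:
    def test_self_guidance_identity(self, rng):
        img = rng.random((9, 9))
        w = agsw_weight_bank(AGSWParams())[(0.0, "full")]
        a, b = fit_window_coeffs(img, img, w, epsilon=0.0)
        assert np.allclose(a, 1.0, atol=1e-8)
        assert np.allclose(b, 0.0, atol=1e-8)

    def test_constant_guidance_gives_weighted_mean(self, rng):
        img = rng.random((9, 9))
        w = agsw_weight_bank(AGSWParams())[(0.0, "full")]
        from scipy.ndimage import correlate

        a, b = fit_window_coeffs(img, np.full((9, 9), 0.3), w, epsilon=1e-3)
        assert np.allclose(a, 0.0, atol=1e-12)
        assert np.allclose(b, correlate(img, w, mode="nearest"), atol=1e-12)

    @pytest.mark.parametrize("loss_form", ["standard", "literal"])
    def test_matches_normal_equation_oracle(self, rng, loss_form):
        """Interior coefficients equal a dense weighted-least-squares
        solve on the corresponding 9x9 window."""
        params = AGSWParams(radius=4, epsilon=0.01, loss_form=loss_form)
        bank = agsw_weight_bank(params)
        img = rng.random((15, 15))
        guide = rng.random((15, 15))
        for key in [(0.0, "full"), (45.0, "left"), (135.0, "se")]:
            w = bank[key]
            a, b = fit_window_coeffs(img, guide, w, params.epsilon, loss_form)
            centre = 7  # interior: window fully inside the image
            sl = slice(centre - 4, centre + 5)
            a_ref, b_ref = brute_force_coeffs(
                img[sl, sl], guide[sl, sl], w, params.epsilon, loss_form
            )
            assert abs(a[centre, centre] - a_ref) < 1e-10
            assert abs(b[centre, centre] - b_ref) < 1e-10

    def test_literal_form_differs_only_by_minus_a(self, rng):
        img, guide = rng.random((11, 11)), rng.random((11, 11))
        w = agsw_weight_bank(AGSWParams())[(90.0, "full")]
        a_s, b_s = fit_window_coeffs(img, guide, w, 0.01, "standard")
        a_l, b_l = fit_window_coeffs(img, guide, w, 0.01, "literal")
        assert np.allclose(a_s, a_l, atol=1e-14)
        assert np.allclose(b_l, b_s - a_s, atol=1e-12)

    def test_gain_shrinks_with_epsilon(self, rng):
        img, guide = rng.random((11, 11)), rng.random((11, 11))
        w = agsw_weight_bank(AGSWParams())[(0.0, "full")]
        prev = None
        for eps in [0.0, 1e-3, 1e-1, 10.0]:
            a, _ = fit_window_coeffs(img, guide, w, eps)
            if prev is not None:
                assert np.all(np.abs(a) <= prev + 1e-15)
            prev = np.abs(a)
        a_huge, _ = fit_window_coeffs(img, guide, w, 1e12)
        assert np.allclose(a_huge, 0.0, atol=1e-9)

    def test_nonfinite_rejected(self):
        w = agsw_weight_bank(AGSWParams())[(0.0, "full")]
        bad = np.full((9, 9), np.nan)
        with pytest.raises(ValueError):
            fit_window_coeffs(bad, bad, w, 0.01)


class TestSideWindowSelection:
    def _coeffs_and_masks(self, img, guide, params):
        bank = agsw_weight_bank(params)
        masks = {n: bank[(0.0, n)] for n in SIDE_WINDOWS}
        coeffs = {
            n: fit_window_coeffs(img, guide, m, params.epsilon)
            for n, m in masks.items()
        }
        return coeffs, masks

    def test_uniform_region_selects_full(self):
        img = np.full((11, 11), 0.5)
        guide = img.copy()
        coeffs, masks = self._coeffs_and_masks(img, guide, AGSWParams())
        sel = select_side_window(img, guide, coeffs, masks)
        assert np.all(sel == SIDE_WINDOWS.index("full"))

    def test_step_edge_windows_do_not_straddle(self, rng):
        """Near an ideal vertical step, the chosen one-sided window's
        reconstruction error (enumerated over all 9) avoids mixing."""
        img = np.where(np.arange(17)[None, :] >= 8, 0.9, 0.1) * np.ones((17, 17))
        img = img + rng.normal(0, 1e-3, img.shape)
        guide = compute_gradient_guidance(img).pixels
        params = AGSWParams(epsilon=1e-6)
        coeffs, masks = self._coeffs_and_masks(img, guide, params)
        sel = select_side_window(img, guide, coeffs, masks)
        # just left of the edge, windows reaching right are bad fits
        left_names = {SIDE_WINDOWS.index(n) for n in ("left", "nw", "sw")}
        right_names = {SIDE_WINDOWS.index(n) for n in ("right", "ne", "se")}
        assert set(sel[5:12, 7]) <= left_names
        assert set(sel[5:12, 8]) <= right_names

    def test_impulse_neighbours_prefer_away_facing_windows(self):
        """Next to a single-pixel impulse on a flat background, the
        side window facing away from the impulse reconstructs the flat
        signal exactly, strictly beating the full window (brute-force
        error comparison over all 9 windows)."""
        img = np.zeros((13, 13))
        img[6, 6] = 1.0
        guide = compute_gradient_guidance(img).pixels
        params = AGSWParams(epsilon=1e-6)
        coeffs, masks = self._coeffs_and_masks(img, guide, params)
        from btc.enhance import _reconstruction_error

        for px, away in [((6, 4), "left"), ((6, 8), "right"),
                         ((4, 6), "up"), ((8, 6), "down")]:
            errors = {
                n: _reconstruction_error(img, guide, masks[n], *coeffs[n])[px]
                for n in SIDE_WINDOWS
            }
            assert errors[away] < errors["full"] - 1e-6
            assert min(errors, key=errors.get) != "full"

    def test_selection_matches_enumeration_oracle(self, rng):
        """The vectorized per-pixel selection equals an independent
        brute-force enumeration of the 9 window errors."""
        img = rng.random((11, 11))
        guide = compute_gradient_guidance(img).pixels
        params = AGSWParams(epsilon=1e-3)
        coeffs, masks = self._coeffs_and_masks(img, guide, params)
        sel = select_side_window(img, guide, coeffs, masks)
        from btc.enhance import _reconstruction_error

        for i, j in [(0, 0), (5, 5), (10, 3), (2, 9)]:
            errs = [
                _reconstruction_error(img, guide, masks[n], *coeffs[n])[i, j]
                for n in SIDE_WINDOWS
            ]
            assert sel[i, j] == int(np.argmin(errs))


class TestAggregation:
    def test_identical_coefficients_preserved(self):
        masks = {n: agsw_weight_bank(AGSWParams())[(0.0, n)]
                 for n in SIDE_WINDOWS}
        a = np.full((10, 10), 0.7)
        b = np.full((10, 10), -0.2)
        sel = np.zeros((10, 10), dtype=int)
        out = aggregate_coeffs(a, b, sel, masks)
        assert np.allclose(out.a, 0.7, atol=1e-12)
        assert np.allclose(out.b, -0.2, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        """Aggregated fields equal a naive per-pixel summation over all
        covering windows on a random 8x8 instance."""
        params = AGSWParams(radius=2)
        masks = {n: agsw_weight_bank(params)[(0.0, n)] for n in SIDE_WINDOWS}
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        sel = rng.integers(0, len(SIDE_WINDOWS), (8, 8))
        out = aggregate_coeffs(a, b, sel, masks)

        r = 2
        a_pad = np.pad(a, r, mode="edge")
        b_pad = np.pad(b, r, mode="edge")
        sel_pad = np.pad(sel, r, mode="edge")
        H = 8 + 2 * r
        for i, j in [(0, 0), (3, 4), (7, 7), (1, 6)]:
            num_a = num_b = xi = 0.0
            ip, jp = i + r, j + r
            for ki in range(H):
                for kj in range(H):
                    oi, oj = ip - ki, jp - kj
                    if abs(oi) > r or abs(oj) > r:
                        continue
                    m = masks[SIDE_WINDOWS[sel_pad[ki, kj]]]
                    wgt = m[oi + r, oj + r]
                    num_a += wgt * a_pad[ki, kj]
                    num_b += wgt * b_pad[ki, kj]
                    xi += wgt
            assert abs(out.a[i, j] - num_a / xi) < 1e-12
            assert abs(out.b[i, j] - num_b / xi) < 1e-12


class TestApplyAndEndToEnd:
    def test_identity_coefficients(self, rng):
        y = rng.random((6, 6))
        from btc.enhance import FilterCoeffs

        z = apply_guided_filter(y, FilterCoeffs(a=np.ones((6, 6)),
                                                b=np.zeros((6, 6))))
        assert np.array_equal(z, y)

    def test_pure_smoothing_limit(self, rng):
        y = rng.random((6, 6))
        from btc.enhance import FilterCoeffs

        b = rng.random((6, 6))
        z = apply_guided_filter(y, FilterCoeffs(a=np.zeros((6, 6)), b=b))
        assert np.array_equal(z, b)

    def test_denoises_flat_regions_preserves_edge(self, rng):
        step = np.where(np.arange(48)[None, :] >= 24, 0.8, 0.2) * np.ones((48, 48))
        noisy = np.clip(step + rng.normal(0, 0.05, step.shape), 0, 1)
        z, _ = agsw_filter(noisy)
        assert z[:, :20].var() < noisy[:, :20].var()
        assert z[:, 28:].var() < noisy[:, 28:].var()
        edge_in = noisy[:, 28:].mean() - noisy[:, :20].mean()
        edge_out = z[:, 28:].mean() - z[:, :20].mean()
        assert abs(edge_out - edge_in) < 0.1 * abs(edge_in)

    def test_idempotent_on_constant_image(self):
        img = np.full((20, 20), 0.5)
        z, _ = agsw_filter(img, AGSWParams(epsilon=1e-3))
        assert np.allclose(z, img, atol=1e-10)


class TestMorphologicalCleanup:
    def test_speckles_removed_single_component(self):
        img = generate_phantom(PhantomSpec(64, "glioma", noise_sd=0.0,
                                           seed=3)).pixels.copy()
        rng = np.random.default_rng(0)
        for _ in range(12):  # bright speckles outside the brain
            r, c = rng.integers(0, 6), rng.integers(0, 64)
            img[r, c] = 1.0
        mask, masked = morphological_cleanup(img)
        from skimage.measure import label

        assert label(mask).max() == 1
        assert not mask[:3, :].any()  # speckle band excluded
        assert mask.shape == img.shape and masked.shape == img.shape

    def test_all_dark_image_full_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask, _ = morphological_cleanup(np.zeros((16, 16)))
        assert mask.all()

    def test_idempotent(self):
        img = generate_phantom(PhantomSpec(64, "meningioma", seed=9)).pixels
        mask1, masked1 = morphological_cleanup(img)
        mask2, masked2 = morphological_cleanup(masked1)
        assert np.array_equal(mask1, mask2)
        assert np.array_equal(masked1, masked2)

    def test_invalid_structuring_element(self):
        with pytest.raises(ValueError):
            StructuringElement(shape="hexagon")
        with pytest.raises(ValueError):
            StructuringElement(radius=0)
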