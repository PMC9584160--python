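"""Linear-combination fitting: NNLS, fit statistics, maps, combinatorics."""

import itertools
import math

import numpy as np
import pytest

from specstack.core import ReferenceLibrary, Spectrum
from specstack.lcf import (
    combinatorial_fit,
    fit_pixelwise,
    fit_spectrum,
    fit_stats,
    flag_spurious_components,
    nnls_coeffs,
    oxidation_state_fraction,
)
from specstack.preprocess import add_gaussian_noise


def _spec(e, y, name="s", normalized=True):
    return Spectrum(np.asarray(e, float), np.asarray(y, float), name=name,
                    normalized=normalized)


class TestNNLS:
    def test_exact_mixture(self):
        e = np.linspace(7.0, 7.2, 20)
        r1 = _spec(e, np.linspace(0, 1, 20), "r1")
        r2 = _spec(e, np.cos(np.arange(20.0)) + 2, "r2")
        data = _spec(e, 0.5 * r1.intensities + 0.5 * r2.intensities)
        coeffs, resid = nnls_coeffs(data, [r1, r2])
        np.testing.assert_allclose(coeffs, [0.5, 0.5], atol=1e-10)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_pure_reference(self):
        e = np.linspace(7.0, 7.2, 20)
        r1 = _spec(e, np.linspace(0, 1, 20), "r1")
        r2 = _spec(e, np.cos(np.arange(20.0)) + 2, "r2")
        coeffs, _ = nnls_coeffs(_spec(e, r1.intensities), [r1, r2])
        np.testing.assert_allclose(coeffs, [1.0, 0.0], atol=1e-10)

    def test_matches_brute_force_grid(self, rng):
        # exhaustive grid over c in [0, 2]^2, step 1e-3, as an independent
        # oracle for the convex NNLS optimum
        e = np.linspace(7.0, 7.4, 5)
        A = rng.random((5, 2)) + 0.1
        d = rng.random(5) * 1.5
        coeffs, _ = nnls_coeffs(
            _spec(e, d), [_spec(e, A[:, 0], "a"), _spec(e, A[:, 1], "b")]
        )
        grid = np.arange(0, 2.0 + 1e-9, 1e-3)
        G = A.T @ A
        b = A.T @ d
        c1, c2 = np.meshgrid(grid, grid, indexing="ij")
        obj = (
            c1**2 * G[0, 0] + 2 * c1 * c2 * G[0, 1] + c2**2 * G[1, 1]
            - 2 * (c1 * b[0] + c2 * b[1])
        )
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        np.testing.assert_allclose(coeffs, [grid[i], grid[j]], atol=2e-3)

    def test_never_worse_than_clipped_unconstrained(self, rng):
        e = np.linspace(7.0, 7.4, 12)
        A = rng.random((12, 3))
        d = rng.random(12)
        refs = [_spec(e, A[:, i], f"r{i}") for i in range(3)]
        coeffs, resid = nnls_coeffs(_spec(e, d), refs)
        unconstrained = np.clip(np.linalg.lstsq(A, d, rcond=None)[0], 0, None)
        assert np.sum(resid**2) <= np.sum((d - A @ unconstrained) ** 2) + 1e-12

    def test_grid_mismatch(self):
        r = _spec(np.linspace(7.0, 7.2, 10), np.ones(10), "r")
        d = _spec(np.linspace(7.0, 7.3, 10), np.ones(10))
        with pytest.raises(ValueError, match="grid"):
            nnls_coeffs(d, [r])

    def test_all_zero_data(self):
        e = np.linspace(7.0, 7.2, 10)
        coeffs, _ = nnls_coeffs(_spec(e, np.zeros(10)), [_spec(e, np.ones(10), "r")])
        np.testing.assert_array_equal(coeffs, [0.0])


class TestFitStats:
    def test_perfect_fit(self):
        assert fit_stats(np.ones(5), np.ones(5), 1) == (0.0, 0.0)

    def test_zero_model_r_factor_one(self):
        d = np.array([1.0, 2.0, 3.0])
        r, _ = fit_stats(d, np.zeros(3), 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed_values(self):
        r, chi2 = fit_stats(np.array([1.0, 2.0]), np.array([1.0, 1.0]), 1)
        assert r == pytest.approx(0.2)
        assert chi2 == pytest.approx(1.0)

    def test_zero_data_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            fit_stats(np.zeros(3), np.ones(3), 1)


class TestFitSpectrum:
    def test_phantom_mean_fractions(self, model_phantom):
        _, stack, truth = model_phantom
        result = fit_spectrum(stack.mean_spectrum(), truth.library)
        np.testing.assert_allclose(
            result.fractions, truth.global_fractions, atol=0.02
        )

    def test_single_reference_identity(self, library11):
        ref = library11[library11.names[0]]
        result = fit_spectrum(ref, [ref], normalize_inputs=False)
        assert result.fractions[0] == pytest.approx(1.0)
        assert result.r_factor < 1e-6

    def test_pre_edge_only_window_errors(self, library11):
        ref = library11[library11.names[0]]
        with pytest.raises(ValueError, match="window"):
            fit_spectrum(ref, list(library11), window=(7.05, 7.06))


class TestFitPixelwise:
    def test_dominant_phase_on_pure_pixels(self, model_phantom):
        _, stack, truth = model_phantom
        maps = fit_pixelwise(stack, truth.library)
        dominant = maps.dominant_reference()
        true_label = truth.dominant_phase()
        pure = (truth.purity() > 0.999) & (true_label >= 0) & (dominant >= 0)
        accuracy = (dominant[pure] == true_label[pure]).mean()
        assert accuracy > 0.99

    def test_background_pixels_zero(self, model_phantom):
        _, stack, truth = model_phantom
        maps = fit_pixelwise(stack, truth.library)
        bg = maps.background.data
        assert bg.any()
        assert np.all(maps.coefficient_maps[:, bg] == 0)

    def test_noise_scale3_fractions_stable(self, model_phantom):
        _, stack, truth = model_phantom
        clean = fit_pixelwise(stack, truth.library).spectral_fractions
        noisy_stack = add_gaussian_noise(stack, 3.0, seed=5)
        noisy = fit_pixelwise(noisy_stack, truth.library).spectral_fractions
        np.testing.assert_allclose(noisy, clean, atol=0.05)

    def test_agrees_with_mean_spectrum_fit(self, model_phantom):
        # the per-pixel map pathway and the single summed-spectrum pathway
        # must tell the same abundance story
        _, stack, truth = model_phantom
        maps = fit_pixelwise(stack, truth.library)
        summed = fit_spectrum(stack.mean_spectrum(), truth.library)
        np.testing.assert_allclose(
            maps.spectral_fractions, summed.fractions, atol=0.02
        )

    def test_all_background_errors(self, library11):
        from specstack.core import EnergyStack

        stack = EnergyStack(
            np.linspace(7.08, 7.20, 20), np.zeros((20, 4, 4)) + 0.0
        )
        with pytest.raises(ValueError):
            fit_pixelwise(stack, library11, background_threshold=2.0)


class TestCombinatorial:
    def test_enumeration_count(self, model_phantom, library11):
        _, stack, _ = model_phantom
        ranking = combinatorial_fit(
            stack.mean_spectrum(), library11, sizes=range(1, 6)
        )
        expected = sum(math.comb(11, s) for s in range(1, 6))
        assert expected == 1023
        assert ranking.total_evaluated == expected
        assert len(ranking.rows) == expected - ranking.n_failed
        chi2 = [r.reduced_chi2 for r in ranking.rows]
        assert chi2 == sorted(chi2)
        subsets = {r.subset for r in ranking.rows}
        assert len(subsets) == len(ranking.rows)

    def test_single_member_recovered(self, library11):
        name = library11.names[2]
        ranking = combinatorial_fit(library11[name], library11, sizes=[1])
        assert ranking.rows[0].subset == (name,)
        assert ranking.rows[0].r_factor < 1e-9

    def test_true_subset_dominates_top_ranks(self, library11):
        # noiseless phantom: every top-5 row must contain all four
        # generating references (extras enter only at flagged, few-percent
        # levels), and the suggested clean row is exactly the true subset
        from specstack import synthetic_data as syn

        spec = syn.model_phantom_spec(seed=0, spatial_shape=(48, 48), poisson=False)
        stack, truth = syn.simulate_stack(spec)
        lib = syn.phantom_library(spec, 11)
        ranking = combinatorial_fit(stack.mean_spectrum(), lib, sizes=range(1, 6))
        true_set = set(truth.library.names)
        assert all(true_set <= set(r.subset) for r in ranking.rows[:5])
        suggested = ranking.rows[ranking.suggested_index]
        assert set(suggested.subset) == true_set

    def test_empty_sizes(self, model_phantom, library11):
        _, stack, _ = model_phantom
        with pytest.raises(ValueError, match="empty"):
            combinatorial_fit(stack.mean_spectrum(), library11, sizes=[])


class TestFlagging:
    @staticmethod
    def _row(subset, fractions):
        from specstack.lcf import CombiRanking, CombiRow

        fr = np.asarray(fractions)
        return CombiRow(tuple(subset), fr.copy(), fr, 1e-4, 1e-3)

    def test_small_component_flagged(self):
        from specstack.lcf import CombiRanking

        r1 = self._row("abcde", [0.05, 0.50, 0.18, 0.11, 0.16])
        r2 = self._row("bcde", [0.50, 0.18, 0.12, 0.20])
        ranking = flag_spurious_components(CombiRanking([r1, r2], 2))
        assert ranking.rows[0].flagged == ("a",)
        assert ranking.rows[1].flagged == ()
        assert ranking.suggested_index == 1

    def test_zero_floor_flags_nothing(self):
        from specstack.lcf import CombiRanking

        r1 = self._row("ab", [0.01, 0.99])
        ranking = flag_spurious_components(CombiRanking([r1], 1), fraction_floor=0.0)
        assert ranking.rows[0].flagged == ()
        assert ranking.suggested_index == 0


class TestOxidationState:
    @staticmethod
    def _two_edges():
        e = np.linspace(7.05, 7.25, 200)

        def edge(pos):
            return 0.5 + np.arctan((e - pos) / 0.0015) / np.pi

        a = _spec(e, edge(7.110), "fe2")
        b = _spec(e, edge(7.118), "fe3")
        return e, a, b

    def test_pure_reference(self):
        _, a, b = self._two_edges()
        (fa, fb), _ = oxidation_state_fraction(a, a, b)
        assert (fa, fb) == pytest.approx((1.0, 0.0), abs=1e-8)

    def test_known_blend(self):
        e, a, b = self._two_edges()
        blend = _spec(e, 0.71 * a.intensities + 0.29 * b.intensities)
        (fa, fb), result = oxidation_state_fraction(
            blend, a, b, window=(7.09, 7.16)
        )
        assert fa == pytest.approx(0.71, abs=0.01)
        assert fb == pytest.approx(0.29, abs=0.01)
        assert not result.degenerate

    def test_collinear_references_flagged(self):
        _, a, _ = self._two_edges()
        twin = a.copy(name="twin")
        (_, _), result = oxidation_state_fraction(a, a, twin)
        assert result.degenerate
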