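"""Alignment, normalization, binning, energy subsetting and noise injection."""

import numpy as np
import pytest
from scipy import ndimage

from specstack.core import EnergyStack, ReferenceLibrary, Spectrum
from specstack.preprocess import (
    add_gaussian_noise,
    align_stack,
    bin_stack,
    estimate_noise_sd,
    interpolate_reference,
    normalize_spectrum,
    normalize_stack,
    subset_energies,
)


def blob_frame(shape=(48, 48), seed=4):
    rng = np.random.default_rng(seed)
    frame = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(6):
        cy, cx = rng.uniform(8, shape[0] - 8, 2)
        r = rng.uniform(2, 6)
        frame += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
    return 100 * frame


def arctan_spectrum(e0=7.112, width=0.0015, height=3.0, slope=0.0, offset=0.0):
    e = np.linspace(7.05, 7.25, 200)
    y = offset + slope * (e - e.min()) + height * (
        0.5 + np.arctan((e - e0) / width) / np.pi
    )
    return Spectrum(e, y, name="edge")


class TestAlignment:
    def test_integer_shift_recovered(self):
        ref = blob_frame()
        shifted = np.roll(np.roll(ref, 3, axis=0), -2, axis=1)
        stack = EnergyStack(np.array([7.0, 7.1]), np.stack([ref, shifted]))
        aligned, result = align_stack(stack, reference_index=0, upsample=10)
        np.testing.assert_allclose(result.shifts[1], [3, -2], atol=0.05)
        valid = result.validity.data
        np.testing.assert_allclose(
            aligned.data[1][valid], ref[valid], atol=1e-6
        )

    def test_identical_frames_zero_shift(self):
        ref = blob_frame()
        stack = EnergyStack(
            np.array([7.0, 7.1, 7.2]), np.stack([ref, ref, ref])
        )
        _, result = align_stack(stack, reference_index=0, upsample=10)
        np.testing.assert_array_equal(result.shifts, np.zeros((3, 2)))

    def test_subpixel_shift_recovered(self):
        ref = blob_frame()
        shifted = ndimage.shift(ref, (0.5, -0.5), order=3)
        stack = EnergyStack(
            np.array([7.0, 7.1]), np.stack([ref, np.clip(shifted, 0, None)])
        )
        _, result = align_stack(stack, reference_index=0, upsample=10)
        np.testing.assert_allclose(result.shifts[1], [0.5, -0.5], atol=0.1)

    def test_flat_frame_warns_and_zeroes(self, caplog):
        ref = blob_frame()
        stack = EnergyStack(
            np.array([7.0, 7.1]), np.stack([ref, np.zeros_like(ref)])
        )
        _, result = align_stack(stack, reference_index=0)
        np.testing.assert_array_equal(result.shifts[1], [0, 0])

    def test_validity_mask_shrinks_with_shift(self):
        ref = blob_frame()
        small = ndimage.shift(ref, (1, 0), order=1)
        big = ndimage.shift(ref, (5, 0), order=1)
        e = np.array([7.0, 7.1])
        _, r_small = align_stack(EnergyStack(e, np.stack([ref, small])), 0)
        _, r_big = align_stack(EnergyStack(e, np.stack([ref, big])), 0)
        assert r_big.validity.n_selected < r_small.validity.n_selected


class TestNormalization:
    def test_analytic_edge(self):
        spec = arctan_spectrum(height=3.0, slope=1.5, offset=0.2)
        norm, params = normalize_spectrum(spec)
        e = norm.energies
        post = e > params.e0 + 0.015
        assert np.mean(norm.intensities[post]) == pytest.approx(1.0, abs=0.02)
        grid_step = np.diff(e).max()
        assert abs(params.e0 - 7.112) <= grid_step + 1e-12

    def test_scale_invariance(self):
        spec = arctan_spectrum(height=2.0, slope=0.5)
        n1, _ = normalize_spectrum(spec)
        n2, _ = normalize_spectrum(spec.copy(intensities=spec.intensities * 10))
        np.testing.assert_allclose(n1.intensities, n2.intensities, atol=1e-9)

    def test_idempotent_within_one_percent(self):
        spec = arctan_spectrum(height=5.0)
        once, _ = normalize_spectrum(spec)
        twice, _ = normalize_spectrum(once)
        post = once.energies > 7.13
        np.testing.assert_allclose(
            twice.intensities[post], once.intensities[post], rtol=0.01, atol=0.01
        )

    def test_no_edge_raises(self):
        e = np.linspace(7.05, 7.25, 60)
        flat = Spectrum(e, np.full(60, 2.0) - 0.5 * (e - 7.05))
        with pytest.raises(ValueError):
            normalize_spectrum(flat)

    def test_stack_matches_per_spectrum(self, two_phase_phantom):
        _, stack, _ = two_phase_phantom
        _, params = normalize_spectrum(stack.mean_spectrum())
        norm = normalize_stack(stack, params)
        # a pure pixel's normalized spectrum should match normalizing that
        # pixel's spectrum with the same shared parameters
        y, x = 2, 2
        pix = Spectrum(stack.energies, stack.data[:, y, x])
        direct, _ = normalize_spectrum(pix, params=params)
        np.testing.assert_allclose(
            norm.data[:, y, x], np.clip(direct.intensities, -0.5, None), atol=1e-9
        )
        assert norm.normalized


class TestBinning:
    def test_shape_halves(self):
        stack = EnergyStack(np.array([7.0]), np.ones((1, 160, 160)))
        assert bin_stack(stack, 2).spatial_shape == (80, 80)

    def test_checkerboard_averages_to_half(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        stack = EnergyStack(np.array([7.0]), board[None].astype(float))
        np.testing.assert_allclose(bin_stack(stack, 2).data, 0.5)

    def test_global_mean_conserved_when_divisible(self, model_phantom):
        _, stack, _ = model_phantom
        binned = bin_stack(stack, 2)
        assert binned.data.mean() == pytest.approx(stack.data.mean(), rel=1e-12)

    def test_factor_too_large(self):
        stack = EnergyStack(np.array([7.0]), np.ones((1, 4, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            bin_stack(stack, 5)


def _tiny_library(diff_index=2, n_e=5):
    e = np.linspace(7.0, 7.4, n_e)
    a = np.ones(n_e)
    b = np.ones(n_e)
    b[diff_index] = 0.0
    return ReferenceLibrary(
        {
            "ref_a": Spectrum(e, a, name="ref_a", normalized=True),
            "ref_b": Spectrum(e, b, name="ref_b", normalized=True),
        }
    )


class TestSubsetEnergies:
    def test_list_mode_identity(self, model_phantom):
        _, stack, _ = model_phantom
        out = subset_energies(stack, energies=list(stack.energies))
        np.testing.assert_array_equal(out.energies, stack.energies)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_list_mode_unmatched_energy(self, model_phantom):
        _, stack, _ = model_phantom
        with pytest.raises(ValueError, match="9.9"):
            subset_energies(stack, energies=[9.9])

    def test_auto_selects_discriminating_energy(self):
        lib = _tiny_library(diff_index=2)
        e = np.linspace(7.0, 7.4, 5)
        stack = EnergyStack(e, np.ones((5, 3, 3)))
        out = subset_energies(stack, n=2, library=lib)
        # the only energy where the two references differ must be kept
        assert e[2] in out.energies

    def test_auto_duplicate_reference_invariant(self, model_phantom, library11):
        _, stack, _ = model_phantom
        base = subset_energies(stack, n=6, library=library11)
        entries = {n: library11[n] for n in library11.names}
        entries["dup"] = library11[library11.names[0]].copy(name="dup")
        augmented = ReferenceLibrary(entries)
        again = subset_energies(stack, n=6, library=augmented)
        np.testing.assert_array_equal(base.energies, again.energies)

    def test_auto_monotone_output(self, model_phantom, library11):
        _, stack, _ = model_phantom
        out = subset_energies(stack, n=12, library=library11)
        assert out.n_energies == 12
        assert np.all(np.diff(out.energies) > 0)


class TestNoise:
    @staticmethod
    def _white_noise_stack(rng):
        data = 1000.0 + rng.normal(0, 10, size=(40, 12, 12))
        return EnergyStack(7.0 + 0.001 * np.arange(40), np.clip(data, 0, None))

    def test_deterministic(self, rng):
        stack = self._white_noise_stack(rng)
        a = add_gaussian_noise(stack, 3.0, seed=7)
        b = add_gaussian_noise(stack, 3.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    @pytest.mark.parametrize("scale", [3.0, 10.0])
    def test_noise_sd_scales(self, rng, scale):
        stack = self._white_noise_stack(rng)
        sigma_hat = estimate_noise_sd(stack)
        noisy = add_gaussian_noise(stack, scale, seed=1)
        diff_sd = (noisy.data - stack.data).std()
        assert diff_sd == pytest.approx(scale * sigma_hat, rel=0.10)

    def test_small_scale_approaches_input(self, rng):
        stack = self._white_noise_stack(rng)
        out = add_gaussian_noise(stack, 1e-9, seed=0)
        np.testing.assert_allclose(out.data, stack.data, atol=1e-6)


class TestInterpolation:
    def test_same_grid_identity(self):
        s = arctan_spectrum()
        out = interpolate_reference(s, s.energies)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_midpoint_is_mean(self):
        s = Spectrum(np.array([1.0, 2.0]), np.array([0.0, 4.0]))
        out = interpolate_reference(s, np.array([1.5]))
        assert out.intensities[0] == 2.0

    def test_edge_jump_preserved_on_coarse_grid(self):
        dense = arctan_spectrum(height=1.0)
        coarse = interpolate_reference(dense, np.linspace(7.08, 7.20, 73))
        jump_dense = dense.intensities[-1] - dense.intensities[0]
        jump_coarse = coarse.intensities[-1] - coarse.intensities[0]
        assert jump_coarse == pytest.approx(jump_dense, rel=0.01)

    def test_extrapolation_refused(self):
        s = arctan_spectrum()
        with pytest.raises(ValueError, match="7.4"):
            interpolate_reference(s, np.array([7.4000]))
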