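"""Stack conditioning ahead of decomposition and fitting.

Covers the standard reduction steps for multi-energy XRF mapping:

* rigid per-frame alignment — the focused beam walks on the sample as the
  monochromator moves, so each energy frame must be registered back to a
  reference frame before any per-pixel spectrum is meaningful;
* XANES edge-step normalization (pre-edge line removal, post-edge leveling,
  division by the edge jump) for spectra and whole stacks;
* spatial binning to trade resolution for per-pixel statistics;
* energy-point subsetting, including an automatic selector that keeps the
  energies most discriminative for a given reference library — the
  multi-energy-point acquisition mode some beamlines use instead of a full
  edge scan;
* seeded Gaussian-noise injection for robustness studies;
* linear interpolation of reference spectra onto a stack's energy grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import BinaryMask, EnergyStack, ReferenceLibrary, Spectrum

logger = logging.getLogger("specstack")

__all__ = [
    "AlignmentResult",
    "NormalizationParams",
    "align_stack",
    "normalize_spectrum",
    "normalize_stack",
    "bin_stack",
    "subset_energies",
    "add_gaussian_noise",
    "interpolate_reference",
    "estimate_noise_sd",
]


@dataclass
class AlignmentResult:
    """Per-frame rigid shifts and the pixels still observed at every energy."""

    shifts: np.ndarray  # (E, 2): estimated (dy, dx) drift of each frame
    # relative to the reference, in pixels (the applied correction is the
    # negative of this)
    reference_index: int
    validity: BinaryMask

    def max_shift(self) -> float:
        return float(np.abs(self.shifts).max())


@dataclass
class NormalizationParams:
    """Edge-step normalization model fitted to one spectrum.

    The pre-edge is modeled as a straight line fitted below ``e0``, the
    post-edge as a low-order polynomial above it; the edge step is the gap
    between the two extrapolated at ``e0``.  Ranges are in keV relative to
    ``e0`` (pre entirely below, post entirely above).
    """

    e0: float
    pre_range: tuple[float, float] = (-1.0, -0.020)
    post_range: tuple[float, float] = (0.015, 1.0)
    pre_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(2))
    post_degree: int = 1
    post_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(2))
    edge_step: float = 1.0

    def pre_line(self, energies: np.ndarray) -> np.ndarray:
        return np.polyval(self.pre_coeffs, energies)

    def post_curve(self, energies: np.ndarray) -> np.ndarray:
        return np.polyval(self.post_coeffs, energies)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_stack(
    stack: EnergyStack,
    reference_index: int = -1,
    upsample: int = 10,
) -> tuple[EnergyStack, AlignmentResult]:
    """Register every frame to one reference frame by phase cross-correlation.

    The default reference is the last frame (post-edge, usually the highest
    signal).  Shifts are estimated to 1/``upsample`` pixel and applied by
    linear resampling; pixels shifted in from outside the field are filled
    with zero and excluded from the validity mask, so downstream photometry
    never mixes real and padded counts.
    """
    E = stack.n_energies
    if E < 2:
        raise ValueError("alignment needs at least two frames")
    ref_idx = range(E)[reference_index]
    ref = stack.data[ref_idx]
    shifts = np.zeros((E, 2))
    aligned = np.empty_like(stack.data)
    valid = np.ones(stack.spatial_shape, dtype=bool)
    ones = np.ones(stack.spatial_shape)
    for i in range(E):
        frame = stack.data[i]
        if i == ref_idx:
            aligned[i] = frame
            continue
        if frame.std() == 0:
            logger.warning("frame %d has zero variance; shift forced to (0,0)", i)
            aligned[i] = frame
            continue
        # plain cross-correlation: the spectral-whitening variant is
        # unreliable on smooth, band-limited fluorescence frames
        correction, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample, normalization=None
        )
        shifts[i] = -correction  # estimated drift of frame i vs reference
        aligned[i] = ndimage.shift(frame, correction, order=1, mode="constant", cval=0.0)
        coverage = ndimage.shift(ones, correction, order=1, mode="constant", cval=0.0)
        valid &= coverage > 0.999
    aligned = np.clip(aligned, 0.0, None) if not stack.normalized else aligned
    out = stack.replace(data=aligned)
    out.log(
        f"aligned to frame {ref_idx} (upsample {upsample}), "
        f"max |shift| {np.abs(shifts).max():.2f} px"
    )
    return out, AlignmentResult(shifts, ref_idx, BinaryMask(valid, label="aligned-valid"))


# ---------------------------------------------------------------------------
# XANES normalization
# ---------------------------------------------------------------------------

def _find_e0(energies: np.ndarray, intensities: np.ndarray) -> float:
    """Edge energy as the maximum of the 3-point-smoothed first derivative."""
    smoothed = np.convolve(intensities, np.ones(3) / 3.0, mode="same")
    deriv = np.gradient(smoothed, energies)
    # exclude endpoints where the smoothing window is truncated
    interior = slice(1, -1) if energies.size > 4 else slice(None)
    idx = int(np.argmax(deriv[interior])) + (1 if energies.size > 4 else 0)
    return float(energies[idx])


def _window(energies: np.ndarray, e0: float, rel_range: tuple[float, float]) -> np.ndarray:
    lo, hi = e0 + rel_range[0], e0 + rel_range[1]
    return (energies >= lo) & (energies <= hi)


def normalize_spectrum(
    spec: Spectrum,
    params: NormalizationParams | None = None,
    e0: float | None = None,
    pre_range: tuple[float, float] = (-1.0, -0.020),
    post_range: tuple[float, float] = (0.015, 1.0),
    post_degree: int = 1,
) -> tuple[Spectrum, NormalizationParams]:
    """Edge-step normalize a XANES spectrum.

    With ``params`` given, applies that model unchanged (shared-parameter
    normalization, e.g. all pixels of one stack).  Otherwise fits: E0 from
    the smoothed-derivative maximum (or the ``e0`` override), a straight
    pre-edge line over ``pre_range``, a degree-``post_degree`` post-edge
    polynomial over ``post_range``, edge step = post(E0) - pre(E0), and
    returns ``(raw - pre_line) / step``.
    """
    e = spec.energies
    y = spec.intensities
    if params is None:
        e0_val = float(e0) if e0 is not None else _find_e0(e, y)
        pre_mask = _window(e, e0_val, pre_range) & (e < e0_val)
        post_mask = _window(e, e0_val, post_range) & (e > e0_val)
        if pre_mask.sum() < 2:
            raise ValueError(
                f"pre-edge window {pre_range} relative to E0={e0_val:.4f} keV "
                "covers fewer than 2 points"
            )
        if post_mask.sum() < post_degree + 1:
            raise ValueError(
                f"post-edge window {post_range} relative to E0={e0_val:.4f} keV "
                "has too few points for a degree-"
                f"{post_degree} fit"
            )
        pre_coeffs = np.polyfit(e[pre_mask], y[pre_mask], 1)
        post_coeffs = np.polyfit(e[post_mask], y[post_mask], post_degree)
        step = float(np.polyval(post_coeffs, e0_val) - np.polyval(pre_coeffs, e0_val))
        if step <= 0:
            raise ValueError("no edge detected: non-positive edge step")
        params = NormalizationParams(
            e0=e0_val,
            pre_range=pre_range,
            post_range=post_range,
            pre_coeffs=pre_coeffs,
            post_degree=post_degree,
            post_coeffs=post_coeffs,
            edge_step=step,
        )
    out = (y - params.pre_line(e)) / params.edge_step
    return (
        Spectrum(e.copy(), out, name=spec.name, normalized=True),
        params,
    )


def normalize_stack(
    stack: EnergyStack,
    params: NormalizationParams | None = None,
    floor: float = -0.5,
    clip_zero: bool = False,
) -> EnergyStack:
    """Apply one shared edge-step normalization to every pixel of a stack.

    The model is fitted on the stack's mean spectrum unless given, then the
    same pre-edge line and step divide each pixel spectrum — pixel-wise
    refitting of noisy single-pixel spectra is deliberately avoided.
    Values below ``floor`` are raised to it; ``clip_zero`` floors at 0.
    """
    if params is None:
        _, params = normalize_spectrum(stack.mean_spectrum())
    pre = params.pre_line(stack.energies)[:, None, None]
    data = (stack.data - pre) / params.edge_step
    lo = 0.0 if clip_zero else floor
    data = np.clip(data, lo, None)
    out = stack.replace(data=data, normalized=True)
    out.log(
        f"normalized with shared params (E0={params.e0:.4f} keV, "
        f"step={params.edge_step:.3g}), floor {lo}"
    )
    return out


# ---------------------------------------------------------------------------
# Binning / subsetting / noise
# ---------------------------------------------------------------------------

def bin_stack(stack: EnergyStack, factor: int) -> EnergyStack:
    """Average non-overlapping factor×factor spatial blocks.

    Trailing rows/columns that do not fill a block are dropped (logged).
    Energies are untouched.  Used to boost per-pixel statistics before
    expensive per-pixel fitting.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    ny, nx = stack.spatial_shape
    if factor > ny or factor > nx:
        raise ValueError(f"bin factor {factor} exceeds spatial shape {ny}x{nx}")
    if factor == 1:
        return stack.replace()
    my, mx = ny // factor, nx // factor
    trimmed = stack.data[:, : my * factor, : mx * factor]
    binned = trimmed.reshape(stack.n_energies, my, factor, mx, factor).mean(axis=(2, 4))
    out = stack.replace(data=binned)
    msg = f"binned {factor}x{factor}: {ny}x{nx} -> {my}x{mx}"
    if my * factor != ny or mx * factor != nx:
        msg += f" (dropped {ny - my * factor} rows, {nx - mx * factor} cols)"
    out.log(msg)
    return out


def _library_matrix(library: ReferenceLibrary, energies: np.ndarray) -> np.ndarray:
    """References interpolated to a grid, deduplicated, as (m, E) rows."""
    rows = []
    for ref in library:
        rows.append(interpolate_reference(ref, energies).intensities)
    mat = np.array(rows)
    # duplicate spectra contribute zero pairwise distance everywhere and
    # would defeat a max-min criterion; keep one representative of each
    uniq: list[np.ndarray] = []
    for row in mat:
        if not any(np.allclose(row, u) for u in uniq):
            uniq.append(row)
    return np.array(uniq)


def _min_pairwise_distance(mat: np.ndarray, idx: list[int]) -> float:
    sub = mat[:, idx]
    best = np.inf
    for a, b in itertools.combinations(range(sub.shape[0]), 2):
        d = float(np.linalg.norm(sub[a] - sub[b]))
        best = min(best, d)
    return best


def subset_energies(
    stack: EnergyStack,
    energies: list[float] | None = None,
    n: int | None = None,
    library: ReferenceLibrary | None = None,
) -> EnergyStack:
    """Keep a subset of the energy points.

    List mode (``energies``): keeps the named energies, matched to the
    nearest grid point within half a grid step.

    Auto mode (``n`` + ``library``): greedy forward selection of ``n``
    energies maximizing the minimum pairwise Euclidean distance between the
    library's reference spectra restricted to the chosen energies — i.e. the
    points where the candidate phases are most distinguishable, emulating a
    multi-energy-point acquisition design.
    """
    grid = stack.energies
    if energies is not None:
        step = np.min(np.diff(grid)) if grid.size > 1 else np.inf
        idx: list[int] = []
        for e in energies:
            j = int(np.argmin(np.abs(grid - e)))
            if abs(grid[j] - e) > step / 2:
                raise ValueError(f"requested energy {e} keV not on the stack grid")
            idx.append(j)
        idx = sorted(set(idx))
    else:
        if n is None or library is None:
            raise ValueError("auto mode needs both n and a reference library")
        if not 2 <= n <= stack.n_energies:
            raise ValueError(f"n must be in [2, {stack.n_energies}]")
        mat = _library_matrix(library, grid)
        if mat.shape[0] < 2:
            raise ValueError("auto selection needs >= 2 distinct references")
        chosen: list[int] = []
        remaining = list(range(grid.size))
        while len(chosen) < n:
            best_j, best_score = remaining[0], -np.inf
            for j in remaining:
                score = _min_pairwise_distance(mat, chosen + [j])
                if score > best_score:
                    best_j, best_score = j, score
            chosen.append(best_j)
            remaining.remove(best_j)
        idx = sorted(chosen)
    out = stack.replace(energies=grid[idx], data=stack.data[idx])
    out.log(f"energy subset: {stack.n_energies} -> {len(idx)} points")
    return out


def estimate_noise_sd(stack: EnergyStack) -> float:
    """Baseline noise level of a stack.

    Per pixel: the SD of the residual after a 3-point moving average along
    energy; the stack-level estimate is the median over pixels, robust to a
    few hot spots.
    """
    kernel = np.ones(3) / 3.0
    smooth = ndimage.convolve1d(stack.data, kernel, axis=0, mode="nearest")
    resid_sd = (stack.data - smooth).std(axis=0)
    # empty background pixels would drag the median to ~0; estimate over
    # signal-bearing pixels (above 2% of the max pixel sum) when any exist
    sums = stack.pixel_sums()
    signal = sums > 0.02 * sums.max()
    if signal.any():
        resid_sd = resid_sd[signal]
    return float(np.median(resid_sd))


def add_gaussian_noise(stack: EnergyStack, scale: float, seed: int = 0) -> EnergyStack:
    """Add zero-mean Gaussian noise with sigma = ``scale`` × baseline SD.

    The baseline SD is :func:`estimate_noise_sd` of the input.  Negative
    results are clipped to zero for raw stacks.  Deterministic per seed.
    """
    if scale <= 0:
        raise ValueError("noise scale must be > 0")
    sigma = scale * estimate_noise_sd(stack)
    rng = np.random.default_rng(seed)
    noisy = stack.data + rng.normal(0.0, sigma, size=stack.data.shape)
    if not stack.normalized:
        noisy = np.clip(noisy, 0.0, None)
    out = stack.replace(data=noisy)
    out.log(f"added Gaussian noise: scale {scale} x baseline SD {sigma / scale:.4g}, seed {seed}")
    return out


def interpolate_reference(spec: Spectrum, target_energies: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a target energy grid.

    Extrapolation beyond one source grid step is refused: reference libraries
    and measured stacks rarely share a grid, but a reference that does not
    cover the scan cannot be used honestly.
    """
    target = np.asarray(target_energies, dtype=float)
    src = spec.energies
    step = np.min(np.diff(src)) if src.size > 1 else 0.0
    lo, hi = src[0] - step, src[-1] + step
    bad = target[(target < lo) | (target > hi)]
    if bad.size:
        raise ValueError(
            f"target energy {bad[0]:.4f} keV outside reference '{spec.name}' "
            f"range [{src[0]:.4f}, {src[-1]:.4f}]"
        )
    out = np.interp(target, src, spec.intensities)
    return Spectrum(target.copy(), out, name=spec.name, normalized=spec.normalized)
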