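"""Linear-combination XANES fitting against a reference library.

An unknown normalized XANES spectrum is modeled as a non-negative weighted
sum of normalized reference standards,

    d(E) ≈ sum_i c_i r_i(E),   c_i >= 0,

solved by non-negative least squares (a convex problem with a global
optimum).  Goodness of fit uses the XAFS conventions:

    r-factor      = sum (d - f)^2 / sum d^2
    reduced chi^2 = sum (d - f)^2 / (n_points - n_params)   (unit weights)

Reported abundances are *spectral fractions*: each coefficient divided by
the coefficient sum.  On top of the single-spectrum fit sit the per-pixel
chemical mapper (coefficient maps over a stack) and the combinatorial
driver, which fits every reference subset of the chosen sizes and ranks
candidates by reduced chi^2 — the screening step used when the sample's
phases are not known a priori.  Components contributing at or below a small
fraction floor are flagged for manual inspection rather than silently
trusted, since near-degenerate references routinely enter top-ranked fits
at the few-percent level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .core import BinaryMask, EnergyStack, ReferenceLibrary, Spectrum
from .preprocess import interpolate_reference, normalize_spectrum

logger = logging.getLogger("specstack")

__all__ = [
    "LCFResult",
    "ChemicalMapSet",
    "CombiRanking",
    "CombiRow",
    "nnls_coeffs",
    "fit_stats",
    "fit_spectrum",
    "fit_pixelwise",
    "combinatorial_fit",
    "flag_spurious_components",
    "oxidation_state_fraction",
]


@dataclass
class LCFResult:
    """One NNLS fit of a spectrum against an ordered reference subset."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    fractions: np.ndarray
    fitted: Spectrum
    r_factor: float
    reduced_chi2: float
    n_points: int
    n_params: int
    window: tuple[float, float] | None = None
    degenerate: bool = False


@dataclass
class ChemicalMapSet:
    """Per-reference coefficient maps over a stack, with fit diagnostics."""

    names: tuple[str, ...]
    coefficient_maps: np.ndarray  # (m, Y, X), >= 0
    spectral_fractions: np.ndarray  # (m,), sums to 1 over fitted pixels
    background: BinaryMask
    r_factor_map: np.ndarray  # (Y, X); NaN on background

    def dominant_reference(self) -> np.ndarray:
        """Index map of the largest-coefficient reference (-1 on background)."""
        labels = np.argmax(self.coefficient_maps, axis=0)
        labels[self.background.data] = -1
        return labels


@dataclass
class CombiRow:
    subset: tuple[str, ...]
    coefficients: np.ndarray
    fractions: np.ndarray
    r_factor: float
    reduced_chi2: float
    flagged: tuple[str, ...] = ()


@dataclass
class CombiRanking:
    """All evaluated reference subsets, best (lowest reduced chi^2) first."""

    rows: list[CombiRow]
    total_evaluated: int
    n_failed: int = 0
    suggested_index: int | None = None

    def to_table(self):
        """Ranking as a DataFrame mirroring the standard report columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "subset": [", ".join(r.subset) for r in self.rows],
                "fractions": [
                    "(" + ", ".join(f"{x:.2f}" for x in r.fractions) + ")" for r in self.rows
                ],
                "r_factor": [r.r_factor for r in self.rows],
                "reduced_chi2": [r.reduced_chi2 for r in self.rows],
                "flagged": [", ".join(r.flagged) for r in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def nnls_coeffs(
    data: Spectrum, refs: list[Spectrum]
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative least-squares coefficients of ``data`` on ``refs``.

    All spectra must share one energy grid.  Returns (coefficients,
    residual vector).  The problem is convex, so the solution is the global
    optimum.
    """
    if not refs:
        raise ValueError("need at least one reference")
    for r in refs:
        if r.energies.shape != data.energies.shape or not np.allclose(
            r.energies, data.energies
        ):
            raise ValueError(
                f"reference '{r.name}' is not on the data energy grid; "
                "interpolate first"
            )
    A = np.column_stack([r.intensities for r in refs])
    coeffs, _ = _scipy_nnls(A, data.intensities)
    residual = data.intensities - A @ coeffs
    return coeffs, residual


def fit_stats(
    data: np.ndarray, fitted: np.ndarray, n_params: int
) -> tuple[float, float]:
    """(r-factor, reduced chi^2) of a fit, XAFS conventions, unit weights."""
    data = np.asarray(data, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if data.shape != fitted.shape:
        raise ValueError("data and fitted lengths differ")
    n = data.size
    if n <= n_params:
        raise ValueError(f"need n_points ({n}) > n_params ({n_params})")
    ss = float(np.sum((data - fitted) ** 2))
    denom = float(np.sum(data**2))
    if denom == 0:
        raise ValueError("r-factor undefined: sum of squared data is zero")
    return ss / denom, ss / (n - n_params)


def _fractions(coeffs: np.ndarray) -> np.ndarray:
    total = coeffs.sum()
    return coeffs / total if total > 0 else np.zeros_like(coeffs)


def _apply_window(
    energies: np.ndarray, window: tuple[float, float] | None
) -> np.ndarray:
    if window is None:
        return np.ones_like(energies, dtype=bool)
    lo, hi = window
    return (energies >= lo) & (energies <= hi)


def _renormalize_like(spec: Spectrum, params, data_energies: np.ndarray) -> Spectrum:
    """Re-level a normalized reference on the data's pre-edge window.

    References normalized on their own grids carry slightly different
    pre-edge baselines than the data; refitting each reference's pre-edge
    line over the *same absolute window* used for the data makes the
    baseline treatment consistent, which matters because the references are
    mutually correlated and a percent-level baseline tilt redistributes
    their coefficients.  Only the line is removed — each reference keeps its
    unit edge step, so coefficient ratios remain spectral fractions.  Falls
    back to the input when the window is unusable for this spectrum.
    """
    e = spec.energies
    y = spec.intensities
    lo = data_energies.min()
    pre = (
        (e >= max(params.e0 + params.pre_range[0], lo))
        & (e <= params.e0 + params.pre_range[1])
    )
    if pre.sum() < 2:
        return spec
    pre_coeffs = np.polyfit(e[pre], y[pre], 1)
    return Spectrum(
        e.copy(), y - np.polyval(pre_coeffs, e),
        name=spec.name, normalized=True,
    )


# ---------------------------------------------------------------------------
# Spectrum-level fitting
# ---------------------------------------------------------------------------

def fit_spectrum(
    data: Spectrum,
    refs: list[Spectrum] | ReferenceLibrary,
    normalize_inputs: bool = True,
    window: tuple[float, float] | None = None,
) -> LCFResult:
    """Linear-combination fit of one spectrum against normalized references.

    References are interpolated onto the data grid; the fit may be
    restricted to an energy ``window`` (keV bounds).  With
    ``normalize_inputs`` (default) a not-yet-normalized data spectrum is
    edge-step normalized first, so coefficients are directly spectral
    weights.
    """
    ref_list = list(refs)
    for r in ref_list:
        if not r.normalized:
            raise ValueError(f"reference '{r.name}' is not normalized")
    if normalize_inputs and not data.normalized:
        data, params = normalize_spectrum(data)
        ref_list = [_renormalize_like(r, params, data.energies) for r in ref_list]
    sel = _apply_window(data.energies, window)
    n_params = len(ref_list)
    if sel.sum() <= n_params:
        raise ValueError(
            f"fit window leaves {int(sel.sum())} points for {n_params} "
            "parameters — empty or degenerate window"
        )
    grid = data.energies[sel]
    d = Spectrum(grid, data.intensities[sel], name=data.name, normalized=data.normalized)
    interp = [interpolate_reference(r, grid) for r in ref_list]
    coeffs, _ = nnls_coeffs(d, interp)
    A = np.column_stack([r.intensities for r in interp])
    fitted_vals = A @ coeffs
    r_factor, red_chi2 = fit_stats(d.intensities, fitted_vals, n_params)
    return LCFResult(
        names=tuple(r.name for r in ref_list),
        coefficients=coeffs,
        fractions=_fractions(coeffs),
        fitted=Spectrum(grid.copy(), fitted_vals, name=f"fit[{data.name}]", normalized=True),
        r_factor=r_factor,
        reduced_chi2=red_chi2,
        n_points=int(sel.sum()),
        n_params=n_params,
        window=window,
    )


# ---------------------------------------------------------------------------
# Per-pixel chemical mapping
# ---------------------------------------------------------------------------

def fit_pixelwise(
    stack: EnergyStack,
    refs: list[Spectrum] | ReferenceLibrary,
    background_threshold: float = 0.02,
    window: tuple[float, float] | None = None,
) -> ChemicalMapSet:
    """NNLS-fit every foreground pixel spectrum; build chemical maps.

    Pixels whose summed intensity falls below ``background_threshold`` times
    the maximum pixel sum are treated as background (no element present, no
    fit).  Raw pixel spectra are fitted against the normalized references —
    the overall intensity scale is absorbed into the coefficients and
    cancels in the fractions, avoiding unstable per-pixel normalization of
    noisy spectra.  Global spectral fractions are each reference's share of
    the total fitted coefficient weight.
    """
    ref_list = list(refs)
    for r in ref_list:
        if not r.normalized:
            raise ValueError(f"reference '{r.name}' is not normalized")
    sums = stack.pixel_sums()
    fg = (sums > 0) & (sums >= background_threshold * sums.max())
    if not fg.any():
        raise ValueError("every pixel falls below the background threshold")
    sel = _apply_window(stack.energies, window)
    grid = stack.energies[sel]
    m = len(ref_list)
    if sel.sum() <= m:
        raise ValueError("fit window leaves too few energies for the references")
    A = np.column_stack(
        [interpolate_reference(r, grid).intensities for r in ref_list]
    )
    ny, nx = stack.spatial_shape
    coeff_maps = np.zeros((m, ny, nx))
    r_map = np.full((ny, nx), np.nan)
    spectra = stack.data[sel]  # (Ew, Y, X)
    ys, xs = np.nonzero(fg)
    for y, x in zip(ys, xs):
        d = spectra[:, y, x]
        c, _ = _scipy_nnls(A, d)
        coeff_maps[:, y, x] = c
        denom = float(np.sum(d**2))
        if denom > 0:
            r_map[y, x] = float(np.sum((d - A @ c) ** 2)) / denom
    total = coeff_maps.sum()
    fractions = (
        coeff_maps.sum(axis=(1, 2)) / total if total > 0 else np.zeros(m)
    )
    return ChemicalMapSet(
        names=tuple(r.name for r in ref_list),
        coefficient_maps=coeff_maps,
        spectral_fractions=fractions,
        background=BinaryMask(~fg, label="background"),
        r_factor_map=r_map,
    )


# ---------------------------------------------------------------------------
# Combinatorial subset screening
# ---------------------------------------------------------------------------

def combinatorial_fit(
    data: Spectrum,
    library: ReferenceLibrary,
    sizes: range | list[int] = range(1, 6),
    max_rank_report: int | None = None,
    normalize_inputs: bool = True,
    window: tuple[float, float] | None = None,
    fraction_floor: float = 0.05,
) -> CombiRanking:
    """Fit every reference subset of the given sizes; rank by reduced chi^2.

    An 11-entry library with sizes 1-5 evaluates sum C(11, s) = 1023
    subsets.  Ties are broken by fewer components (parsimony), then by
    r-factor.  Rows are annotated by :func:`flag_spurious_components` with
    ``fraction_floor``; all rows are kept (``max_rank_report`` only truncates
    the returned list).
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes is empty")
    if max(sizes) > len(library):
        raise ValueError(
            f"subset size {max(sizes)} exceeds library size {len(library)}"
        )
    ref_specs = {n: library[n] for n in library.names}
    if normalize_inputs and not data.normalized:
        data, params = normalize_spectrum(data)
        ref_specs = {
            n: _renormalize_like(s, params, data.energies)
            for n, s in ref_specs.items()
        }
    sel = _apply_window(data.energies, window)
    grid = data.energies[sel]
    d = data.intensities[sel]
    names = library.names
    cols = {
        n: interpolate_reference(ref_specs[n], grid).intensities for n in names
    }
    denom = float(np.sum(d**2))
    if denom == 0:
        raise ValueError("data spectrum is all zero")
    rows: list[CombiRow] = []
    total = 0
    failed = 0
    for s in sizes:
        for subset in itertools.combinations(names, s):
            total += 1
            if len(grid) <= s:
                failed += 1
                continue
            A = np.column_stack([cols[n] for n in subset])
            try:
                c, _ = _scipy_nnls(A, d)
            except Exception as exc:  # pragma: no cover - nnls rarely fails
                logger.warning("subset %s failed: %s", subset, exc)
                failed += 1
                continue
            ss = float(np.sum((d - A @ c) ** 2))
            rows.append(
                CombiRow(
                    subset=subset,
                    coefficients=c,
                    fractions=_fractions(c),
                    r_factor=ss / denom,
                    reduced_chi2=ss / (len(grid) - s),
                )
            )
    rows.sort(key=lambda r: (r.reduced_chi2, len(r.subset), r.r_factor))
    if max_rank_report is not None:
        rows = rows[:max_rank_report]
    ranking = CombiRanking(rows=rows, total_evaluated=total, n_failed=failed)
    return flag_spurious_components(ranking, fraction_floor=fraction_floor)


def flag_spurious_components(
    ranking: CombiRanking, fraction_floor: float = 0.05
) -> CombiRanking:
    """Mark sub-floor components for inspection; suggest the best clean row.

    A component entering a top-ranked fit at a few percent abundance is as
    likely to be fitting noise as a real minority phase, so rows keep their
    rank but carry an "inspect" flag per offending component; the suggested
    automatic candidate is the highest-ranked row with no flags.
    """
    suggested = None
    for i, row in enumerate(ranking.rows):
        flagged = tuple(
            name
            for name, frac in zip(row.subset, row.fractions)
            if frac <= fraction_floor
        )
        row.flagged = flagged
        if suggested is None and not flagged:
            suggested = i
    ranking.suggested_index = suggested
    return ranking


def oxidation_state_fraction(
    data: Spectrum,
    ref_a: Spectrum,
    ref_b: Spectrum,
    window: tuple[float, float] | None = None,
) -> tuple[tuple[float, float], LCFResult]:
    """Two-reference fit, e.g. Fe(III) vs Fe(II) share of a particle spectrum.

    Returns ``((fraction_a, fraction_b), result)``.  If the two references
    are nearly collinear over the window the split is ill-conditioned; the
    result is flagged ``degenerate`` and a warning logged.
    """
    result = fit_spectrum(data, [ref_a, ref_b], window=window)
    sel = _apply_window(data.energies, window)
    grid = data.energies[sel]
    a = interpolate_reference(ref_a, grid).intensities
    b = interpolate_reference(ref_b, grid).intensities
    if a.std() > 0 and b.std() > 0 and abs(np.corrcoef(a, b)[0, 1]) > 0.999:
        logger.warning(
            "references '%s' and '%s' are nearly collinear over the fit "
            "window; fractions are degenerate",
            ref_a.name,
            ref_b.name,
        )
        result.degenerate = True
    return (float(result.fractions[0]), float(result.fractions[1])), result
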