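"""Phantom generator: energy stacks with known ground truth.

Real multi-energy nano-XRF measurements of mixed mineral aggregates are
facility data; the exact phase fractions of such samples are typically
unknown even to the experimenter.  This module builds the controlled stand-in:
synthetic Fe K-edge XANES standards (arctan edge + Gaussian white lines),
spatial phase-fraction maps (tiles, disjoint blobs, or an overlapping
particle aggregate), and the forward model

    signal(e, y, x) = counts_scale * sum_phase fraction(y, x) * mu_phase(e)

with optional Poisson counting noise and per-energy beam drift.  Every draw
is seeded and bit-reproducible, and the generator returns the ground truth
(fraction maps, pure spectra, global spectral fractions, injected drift)
alongside the stack so estimators can be scored exactly.

Defaults mirror a typical Fe K-edge acquisition: 73 incident energies from
7.08 to 7.20 keV across the edge at 7.112 keV on a 160 x 160 raster, and the
"model" preset uses 4 phases with global spectral fractions
0.50 / 0.20 / 0.12 / 0.18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ElementMap, EnergyStack, ReferenceLibrary, Spectrum

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_reference_set",
    "make_fraction_maps",
    "make_drift_schedule",
    "simulate_stack",
    "simulate_element_maps",
    "phantom_library",
    "model_phantom_spec",
]

FE_K_EDGE_KEV = 7.112
DEFAULT_ENERGIES = np.linspace(7.08, 7.20, 73)
# wider, denser grid for reference standards so they always cover the scan
REFERENCE_GRID = np.linspace(7.05, 7.25, 201)


# ---------------------------------------------------------------------------
# Reference standards
# ---------------------------------------------------------------------------

def _random_xanes(rng: np.random.Generator, energies: np.ndarray, e0: float) -> np.ndarray:
    """One normalized synthetic XANES curve: arctan edge + 1-2 white lines.

    The edge position is jittered within +-4 eV of ``e0``, emulating the
    oxidation-state-dependent edge shift that distinguishes e.g. Fe(II) from
    Fe(III) phases.
    """
    edge = e0 + rng.uniform(-0.004, 0.004)
    width = rng.uniform(0.0008, 0.002)
    mu = 0.5 + np.arctan((energies - edge) / width) / np.pi
    for _ in range(rng.integers(1, 3)):
        center = edge + rng.uniform(0.002, 0.020)
        height = rng.uniform(0.2, 0.9)
        sigma = rng.uniform(0.0015, 0.004)
        mu = mu + height * np.exp(-0.5 * ((energies - center) / sigma) ** 2)
    return mu


def make_reference_set(
    n: int,
    seed: int = 0,
    energies: np.ndarray | None = None,
    e0: float = FE_K_EDGE_KEV,
    max_pairwise_r: float = 0.995,
) -> ReferenceLibrary:
    """Library of ``n`` distinct normalized synthetic standards.

    Distinctness is enforced by rejection sampling: a draw whose Pearson
    correlation with any accepted spectrum reaches ``max_pairwise_r`` is
    discarded (at most 100 attempts per slot).
    """
    if n < 2:
        raise ValueError("need at least 2 references")
    from .preprocess import normalize_spectrum

    grid = REFERENCE_GRID.copy() if energies is None else np.asarray(energies, dtype=float)
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    while len(accepted) < n:
        for attempt in range(100):
            mu = _random_xanes(rng, grid, e0)
            # run the draw through the package's own edge-step normalization
            # so references and measured data share one convention (the
            # arctan pre-edge tail is removed the same way a fitted pre-edge
            # line removes it from data)
            raw = Spectrum(grid.copy(), mu, name="candidate")
            try:
                norm, _ = normalize_spectrum(raw)
            except ValueError:
                continue
            mu = norm.intensities
            if all(np.corrcoef(mu, prev)[0, 1] < max_pairwise_r for prev in accepted):
                accepted.append(mu)
                break
        else:
            raise RuntimeError(
                f"could not draw {n} references with pairwise r < {max_pairwise_r}"
            )
    specs = {
        f"std_{i + 1:02d}": Spectrum(grid.copy(), mu, name=f"std_{i + 1:02d}", normalized=True)
        for i, mu in enumerate(accepted)
    }
    return ReferenceLibrary(specs, metadata=f"synthetic standards, seed {seed}")


# ---------------------------------------------------------------------------
# Fraction maps
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, radii, angle, rng=None) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ry, rx = radii
    c, s = np.cos(angle), np.sin(angle)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def make_fraction_maps(
    spatial_shape: tuple[int, int],
    k: int,
    geometry: str = "aggregate",
    mixing_fraction: float = 0.0,
    target_fractions: np.ndarray | None = None,
    fill_fraction: float = 0.45,
    seed: int = 0,
) -> tuple[np.ndarray, BinaryMask]:
    """Per-phase fraction maps (k × Y × X, each pixel summing to <= 1).

    geometry:
      * ``tiles`` — k disjoint rectangular tiles covering the field (4 phases
        on a square field gives quadrants); every pixel pure.
      * ``blobs`` — one disjoint ellipse per phase on empty background.
      * ``aggregate`` — many overlapping-in-space elliptical particles grown
        greedily until the occupied area's phase shares match
        ``target_fractions``; ``mixing_fraction`` > 0 smooths phase
        boundaries into mixed pixels, emulating a physically mixed
        nanoparticle aggregate.

    Returns the fraction maps and the background mask (pixels with no phase).
    """
    ny, nx = spatial_shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= mixing_fraction < 1:
        raise ValueError("mixing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if target_fractions is None:
        target = np.full(k, 1.0 / k)
    else:
        target = np.asarray(target_fractions, dtype=float)
        if target.size != k or np.any(target <= 0):
            raise ValueError("target_fractions must have k positive entries")
        target = target / target.sum()

    fractions = np.zeros((k, ny, nx))

    if geometry == "tiles":
        rows = max(1, int(np.floor(np.sqrt(k))))
        cols = int(np.ceil(k / rows))
        edges_y = np.linspace(0, ny, rows + 1).astype(int)
        edges_x = np.linspace(0, nx, cols + 1).astype(int)
        for i in range(k):
            r, c = divmod(i, cols)
            fractions[i, edges_y[r] : edges_y[r + 1], edges_x[c] : edges_x[c + 1]] = 1.0
    elif geometry == "blobs":
        label = -np.ones((ny, nx), dtype=int)
        r_max = min(ny, nx) / (2.5 * np.sqrt(k))
        if r_max < 2:
            raise ValueError(f"{k} blobs cannot fit a {ny}x{nx} field")
        for i in range(k):
            for attempt in range(200):
                center = (rng.uniform(r_max, ny - r_max), rng.uniform(r_max, nx - r_max))
                radii = (rng.uniform(0.5, 1.0) * r_max, rng.uniform(0.5, 1.0) * r_max)
                mask = _ellipse_mask((ny, nx), center, radii, rng.uniform(0, np.pi))
                if not mask.any():
                    continue
                if (label[mask] == -1).all():
                    label[mask] = i
                    break
            else:
                raise RuntimeError(f"could not place disjoint blob {i} of {k}")
            fractions[i] = label == i
    elif geometry == "aggregate":
        label = -np.ones((ny, nx), dtype=int)
        r_lo, r_hi = 0.03 * min(ny, nx), 0.10 * min(ny, nx)
        r_lo = max(r_lo, 1.5)
        r_hi = max(r_hi, r_lo + 1)
        for _ in range(5000):
            occupied = label >= 0
            occ_frac = occupied.mean()
            if occ_frac > 0:
                shares = np.array([(label == i).sum() for i in range(k)]) / occupied.sum()
            else:
                shares = np.zeros(k)
            if occ_frac >= fill_fraction and np.abs(shares - target).max() <= 0.01:
                break
            phase = int(np.argmax(target - shares))
            center = (rng.uniform(0, ny), rng.uniform(0, nx))
            radii = (rng.uniform(r_lo, r_hi), rng.uniform(r_lo, r_hi))
            mask = _ellipse_mask((ny, nx), center, radii, rng.uniform(0, np.pi))
            grow = mask & (label == -1)
            label[grow] = phase
        for i in range(k):
            fractions[i] = label == i
        if mixing_fraction > 0:
            sigma = 3.0 * mixing_fraction
            for i in range(k):
                fractions[i] = ndimage.gaussian_filter(fractions[i], sigma)
            total = fractions.sum(axis=0)
            over = total > 1.0
            fractions[:, over] /= total[over]
    else:
        raise ValueError(f"unknown geometry '{geometry}'")

    background = BinaryMask(fractions.sum(axis=0) < 1e-9, label="background")
    return fractions, background


def make_drift_schedule(n_energies: int, max_shift: float, seed: int = 0) -> np.ndarray:
    """Smooth per-energy (dy, dx) drift, a bounded random walk, in pixels.

    The first frame's shift is zero; the walk is rescaled so the largest
    per-axis excursion equals ``max_shift``.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 1.0, size=(n_energies, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= max_shift / peak
    return walk


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom reproducibly."""

    energies: np.ndarray = field(default_factory=lambda: DEFAULT_ENERGIES.copy())
    spatial_shape: tuple[int, int] = (160, 160)
    n_phases: int = 4
    geometry: str = "aggregate"
    target_fractions: tuple[float, ...] | None = (0.50, 0.20, 0.12, 0.18)
    mixing_fraction: float = 0.0
    counts_scale: float = 1.0e4
    baseline_fraction: float = 0.02
    drift_max: float = 0.0
    poisson: bool = True
    seed: int = 0
    element: str = "Fe"

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.size < 2 or not np.all(np.diff(self.energies) > 0):
            raise ValueError("energy grid must be strictly increasing, length >= 2")
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be > 0")
        if self.target_fractions is not None and len(self.target_fractions) != self.n_phases:
            raise ValueError("target_fractions length must equal n_phases")


@dataclass
class GroundTruth:
    """The oracle: what the phantom actually contains."""

    fraction_maps: np.ndarray  # (k, Y, X)
    spectra: list[Spectrum]  # pure normalized phase spectra
    global_fractions: np.ndarray  # (k,), sums to 1 over phases
    background: BinaryMask
    drift: np.ndarray | None  # (E, 2) or None
    library: ReferenceLibrary  # the k generating standards

    def dominant_phase(self) -> np.ndarray:
        """Label map of the largest-fraction phase (-1 on background)."""
        labels = np.argmax(self.fraction_maps, axis=0)
        labels[self.background.data] = -1
        return labels

    def purity(self) -> np.ndarray:
        """Largest single-phase share of each pixel's total (0 on background)."""
        total = self.fraction_maps.sum(axis=0)
        out = np.zeros_like(total)
        occ = total > 0
        out[occ] = self.fraction_maps.max(axis=0)[occ] / total[occ]
        return out


def model_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The standard 4-phase aggregate preset (fractions 0.50/0.20/0.12/0.18)."""
    kw = dict(seed=seed)
    kw.update(overrides)
    return PhantomSpec(**kw)


def _subseeds(seed: int) -> tuple[int, int, int, int]:
    """(reference, geometry, noise, drift) sub-seeds derived from one seed."""
    root = np.random.SeedSequence(seed)
    return tuple(int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4))


def phantom_library(spec: PhantomSpec, n: int) -> ReferenceLibrary:
    """An ``n``-entry library whose first entries are the phantom's phases.

    Reference draws are sequential, so the first ``spec.n_phases`` standards
    of this library are exactly the phantom's generating spectra; the rest
    act as decoys for combinatorial screening.
    """
    if n < spec.n_phases:
        raise ValueError(f"library size {n} smaller than n_phases {spec.n_phases}")
    s_ref = _subseeds(spec.seed)[0]
    return make_reference_set(max(n, 2), seed=s_ref)


def simulate_stack(spec: PhantomSpec) -> tuple[EnergyStack, GroundTruth]:
    """Generate a phantom stack and its ground truth from a :class:`PhantomSpec`.

    Sub-seeds for the reference draw, geometry, Poisson sampling and drift
    are derived deterministically from ``spec.seed``.
    """
    s_ref, s_geo, s_noise, s_drift = _subseeds(spec.seed)

    library = make_reference_set(max(spec.n_phases, 2), seed=s_ref)
    phase_names = library.names[: spec.n_phases]
    spectra = [library[n] for n in phase_names]
    mu = np.array(
        [np.interp(spec.energies, s.energies, s.intensities) for s in spectra]
    )  # (k, E)

    fractions, background = make_fraction_maps(
        spec.spatial_shape,
        spec.n_phases,
        geometry=spec.geometry,
        mixing_fraction=spec.mixing_fraction,
        target_fractions=spec.target_fractions,
        seed=s_geo,
    )

    # pre-edge of normalized spectra can dip marginally below zero; count
    # rates cannot
    clean = np.clip(spec.counts_scale * np.einsum("ke,kyx->eyx", mu, fractions), 0.0, None)
    if spec.baseline_fraction > 0:
        # energy-independent scatter/background pedestal proportional to the
        # local sample mass; keeps pre-edge frames registrable, as in
        # measured stacks
        clean = clean + (
            spec.baseline_fraction * spec.counts_scale * fractions.sum(axis=0)
        )

    drift = None
    data = clean
    if spec.drift_max > 0:
        drift = make_drift_schedule(spec.energies.size, spec.drift_max, seed=s_drift)
        shifted = np.empty_like(data)
        for i, (dy, dx) in enumerate(drift):
            shifted[i] = ndimage.shift(data[i], (dy, dx), order=1, mode="constant", cval=0.0)
        data = shifted

    if spec.poisson:
        rng = np.random.default_rng(s_noise)
        data = rng.poisson(np.clip(data, 0, None)).astype(float)

    stack = EnergyStack(
        spec.energies.copy(),
        data,
        element=spec.element,
        provenance=[
            f"synthetic phantom: {spec.n_phases} phases, geometry {spec.geometry}, "
            f"counts_scale {spec.counts_scale:g}, poisson {spec.poisson}, "
            f"drift_max {spec.drift_max}, seed {spec.seed}"
        ],
    )
    total = fractions.sum()
    truth = GroundTruth(
        fraction_maps=fractions,
        spectra=[s.copy() for s in spectra],
        global_fractions=fractions.sum(axis=(1, 2)) / total,
        background=background,
        drift=drift,
        library=ReferenceLibrary({n: library[n] for n in phase_names}),
    )
    return stack, truth


def simulate_element_maps(
    truth: GroundTruth,
    stoichiometry: dict[str, np.ndarray],
    counts_scale: float = 1.0,
    poisson: bool = False,
    seed: int = 0,
) -> dict[str, ElementMap]:
    """XRF element maps implied by per-phase elemental weights.

    ``stoichiometry`` maps an element symbol to a length-k weight vector
    (relative line intensity per unit phase fraction).  Phases sharing an
    element with different weight ratios produce the distinct linear branches
    that elemental-correlation scatter analysis exploits.
    """
    k = truth.fraction_maps.shape[0]
    rng = np.random.default_rng(seed)
    out: dict[str, ElementMap] = {}
    for element, weights in stoichiometry.items():
        w = np.asarray(weights, dtype=float)
        if w.size != k:
            raise ValueError(f"element '{element}': expected {k} phase weights, got {w.size}")
        if np.any(w < 0):
            raise ValueError(f"element '{element}': weights must be >= 0")
        data = counts_scale * np.tensordot(w, truth.fraction_maps, axes=(0, 0))
        if poisson:
            data = rng.poisson(data).astype(float)
        out[element] = ElementMap(data, element=element)
    return out
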