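"""Component analysis of energy stacks.

The stack V (E × P, pixels flattened row-major) is modeled as a product of a
few spectrum-like columns and their pixel loadings,

    V ≈ W H,   W: E × k,   H: k × P,   k << E.

The component count k is read off an SVD scree: the smallest k whose
cumulative squared-singular-value fraction reaches a threshold (default
0.90).  NMF is the workhorse factorization because its nonnegativity makes W
columns directly interpretable as XANES-like spectra; PCA, ICA, factor
analysis, truncated SVD and dictionary learning are available for
comparison.  Recovered component spectra are edge-step normalized and
matched to a reference library by Pearson correlation; k-means over
shape-normalized pixel spectra provides a clustering alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import (
    NMF,
    PCA,
    DictionaryLearning,
    FactorAnalysis,
    FastICA,
    TruncatedSVD,
)

from . import preprocess
from .core import EnergyStack, ReferenceLibrary, Spectrum, reshape_from_matrix, reshape_to_matrix

logger = logging.getLogger("specstack")

__all__ = [
    "ScreeResult",
    "ComponentSet",
    "svd_scree",
    "estimate_num_components",
    "decompose",
    "component_spectra",
    "correlation_with_references",
    "cluster_pixels",
    "METHODS",
]

METHODS = ("nmf", "pca", "ica", "fa", "tsvd", "dict")
# PCA-family methods model deviations around a mean; their leading component
# is essentially the mean spectrum and is conventionally dropped for display.
MEAN_CENTERED_METHODS = ("pca", "ica", "fa")


@dataclass
class ScreeResult:
    """Singular values of the flattened stack and their explained fractions."""

    singular_values: np.ndarray  # descending
    fractions: np.ndarray  # sigma_i^2 / sum sigma^2
    cumulative: np.ndarray

    def __post_init__(self):
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)


@dataclass
class ComponentSet:
    """Result of one k-component factorization of a stack."""

    k: int
    W: np.ndarray  # E x k spectral components
    H: np.ndarray  # k x P pixel loadings
    energies: np.ndarray
    spatial_shape: tuple[int, int]
    method: str
    reconstruction_error: float  # ||V - WH||_F / ||V||_F
    seed: int | None = None

    @property
    def maps(self) -> np.ndarray:
        """Loadings folded back to k × Y × X component maps."""
        return reshape_from_matrix(self.H, self.spatial_shape)


def svd_scree(stack: EnergyStack) -> ScreeResult:
    """Singular-value spectrum of the E × P stack matrix.

    Explained fractions use the variance convention sigma_i^2 / sum sigma^2,
    so the scree answers "how much of the stack's energy does a rank-k
    truncation capture".
    """
    V = reshape_to_matrix(stack)
    sv = np.linalg.svd(V, compute_uv=False)
    total = float(np.sum(sv**2))
    fractions = sv**2 / total if total > 0 else np.zeros_like(sv)
    return ScreeResult(sv, fractions, np.cumsum(fractions))


def estimate_num_components(scree: ScreeResult, threshold: float = 0.90) -> int:
    """Smallest k whose cumulative explained fraction reaches ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return int(np.searchsorted(scree.cumulative, threshold) + 1)


def _kmeans_init(
    V: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Nonnegative (W0, H0) from k-means over shape-normalized pixel spectra."""
    sums = V.sum(axis=0)
    fg = sums > 0
    if fg.sum() < k:
        return None
    X = (V[:, fg] / sums[fg]).T
    if np.unique(X, axis=0).shape[0] < k:
        return None
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    labels = np.full(V.shape[1], -1, dtype=int)
    labels[fg] = km.labels_
    W0 = np.zeros((V.shape[0], k))
    H0 = np.zeros((k, V.shape[1]))
    for c in range(k):
        members = labels == c
        W0[:, c] = V[:, members].mean(axis=1) if members.any() else V.mean(axis=1)
        H0[c, members] = 1.0
    eps = 1e-12
    return np.clip(W0, eps, None), np.clip(H0, eps, None)


def _order_by_map_total(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    totals = np.abs(H).sum(axis=1)
    order = np.argsort(totals)[::-1]
    return W[:, order], H[order]


def decompose(
    stack: EnergyStack,
    k: int,
    method: str = "nmf",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> ComponentSet:
    """Factorize a stack into k spectral components and k loading maps.

    NMF uses a deterministic SVD-based nonnegative initialization
    (``nndsvda``) so repeated runs agree; the seed only matters for methods
    with stochastic fits.  Components are ordered by descending total map
    weight.  NMF refuses stacks with negative entries (clip, or use a
    PCA-family method).
    """
    V = reshape_to_matrix(stack)
    E, P = V.shape
    if not 1 <= k <= min(E, P):
        raise ValueError(f"k={k} outside [1, min(E, P)={min(E, P)}]")
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'; choose from {METHODS}")

    mean_term = None
    if method == "nmf":
        if np.any(V < 0):
            raise ValueError(
                "stack has negative entries; clip to zero or use a "
                "PCA-family method for NMF-free decomposition"
            )
        # plain NMF is rotation-ambiguous: mixed spectra can reconstruct as
        # well as the pure ones.  Seeding the factorization from k-means
        # cluster means biases it toward spatially segregated components
        # (standard practice in hyperspectral unmixing); deterministic SVD
        # and seeded random inits serve as restarts, lowest residual wins.
        candidates: list[tuple[np.ndarray | None, np.ndarray | None, str]] = []
        if k >= 2:
            km_init = _kmeans_init(V, k, seed)
            if km_init is not None:
                candidates.append((*km_init, "custom"))
        candidates.append((None, None, "nndsvd"))
        candidates.append((None, None, "random"))
        best = None
        import warnings

        for W0, H0, init in candidates:
            model = NMF(
                n_components=k, init=init, solver="cd", tol=tol,
                max_iter=max_iter, random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if init == "custom":
                    Wc = model.fit_transform(V, W=W0.copy(), H=H0.copy())
                else:
                    Wc = model.fit_transform(V)
            Hc = model.components_
            err = np.linalg.norm(V - Wc @ Hc)
            # earlier candidates (k-means first) are preferred: a later one
            # must improve the residual materially (0.1%) to displace them,
            # since near-tied factorizations differ only by component mixing
            if best is None or err < best[0] * (1 - 1e-3):
                best = (err, Wc, Hc)
        _, W, H = best
    elif method == "pca":
        model = PCA(n_components=k, random_state=seed)
        W = model.fit_transform(V)
        H = model.components_
        mean_term = model.mean_
    elif method == "ica":
        model = FastICA(n_components=k, random_state=seed, max_iter=max_iter, tol=tol)
        W = model.fit_transform(V)
        # FastICA factorizes centered V = sources @ mixing^T; rebuild H so
        # that V ~ W H + mean holds with W the per-energy source signals
        H = np.linalg.pinv(W) @ (V - model.mean_)
        mean_term = model.mean_
    elif method == "fa":
        model = FactorAnalysis(n_components=k, random_state=seed, max_iter=max_iter)
        W = model.fit_transform(V)
        H = np.linalg.pinv(W) @ (V - model.mean_)
        mean_term = model.mean_
    elif method == "tsvd":
        model = TruncatedSVD(n_components=k, random_state=seed)
        W = model.fit_transform(V)
        H = model.components_
    else:  # dict
        model = DictionaryLearning(
            n_components=k, random_state=seed, max_iter=max_iter,
            transform_algorithm="lasso_lars", fit_algorithm="lars",
        )
        W = model.fit_transform(V)
        H = model.components_

    W, H = _order_by_map_total(np.asarray(W, dtype=float), np.asarray(H, dtype=float))
    recon = W @ H
    if mean_term is not None:
        recon = recon + mean_term
    denom = np.linalg.norm(V)
    err = float(np.linalg.norm(V - recon) / denom) if denom > 0 else 0.0
    return ComponentSet(
        k=k, W=W, H=H, energies=stack.energies.copy(),
        spatial_shape=stack.spatial_shape, method=method,
        reconstruction_error=err, seed=seed,
    )


def component_spectra(cs: ComponentSet) -> list[Spectrum]:
    """Columns of W as XANES-normalized spectra, named in map-total order.

    A component with no absorption edge (e.g. a pure-noise component) cannot
    be edge-step normalized; it is returned raw with ``normalized=False``
    and a warning.
    """
    out: list[Spectrum] = []
    for i in range(cs.k):
        raw = Spectrum(cs.energies.copy(), cs.W[:, i].copy(), name=f"component_{i + 1}")
        try:
            norm, _ = preprocess.normalize_spectrum(raw)
            out.append(norm)
        except ValueError as exc:
            logger.warning("component_%d not normalized: %s", i + 1, exc)
            out.append(raw)
    return out


def correlation_with_references(
    spectra: list[Spectrum],
    library: ReferenceLibrary,
    energies: np.ndarray | None = None,
) -> np.ndarray:
    """k × m Pearson correlation matrix of component spectra vs references.

    Spectra and references are compared on a common grid (the first
    spectrum's grid unless ``energies`` is given).  A zero-variance spectrum
    yields NaN entries — explicitly missing, not zero correlation.
    """
    if not spectra:
        raise ValueError("no spectra given")
    grid = np.asarray(energies, dtype=float) if energies is not None else spectra[0].energies
    comp = np.array([np.interp(grid, s.energies, s.intensities) for s in spectra])
    refs = np.array(
        [preprocess.interpolate_reference(r, grid).intensities for r in library]
    )
    out = np.full((comp.shape[0], refs.shape[0]), np.nan)
    for i, c in enumerate(comp):
        if c.std() == 0:
            continue
        for j, r in enumerate(refs):
            if r.std() == 0:
                continue
            out[i, j] = float(np.corrcoef(c, r)[0, 1])
    return out


def cluster_pixels(
    stack: EnergyStack,
    k: int,
    seed: int = 0,
) -> tuple[np.ndarray, list[Spectrum]]:
    """k-means over shape-normalized pixel spectra.

    Each pixel spectrum is divided by its own sum before clustering so
    clusters group spectral shape, not concentration; zero-sum pixels are
    assigned the background label -1.  Returns the Y × X label map and the
    mean raw spectrum of each cluster.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    V = reshape_to_matrix(stack)  # E x P
    sums = V.sum(axis=0)
    fg = sums > 0
    X = (V[:, fg] / sums[fg]).T  # pixels x energies
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct pixel spectra")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    fg_labels = km.fit_predict(X)
    labels = np.full(V.shape[1], -1, dtype=int)
    labels[fg] = fg_labels
    label_map = labels.reshape(stack.spatial_shape)
    means: list[Spectrum] = []
    for c in range(k):
        members = labels == c
        if members.sum() == 0:
            logger.warning("cluster %d is empty", c)
            mean = np.zeros(stack.n_energies)
        else:
            mean = V[:, members].mean(axis=1)
        means.append(Spectrum(stack.energies.copy(), mean, name=f"cluster_{c}"))
    return label_map, means
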