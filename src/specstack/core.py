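"""Domain types and small utilities shared by every stage of the workflow.

The central object is the :class:`EnergyStack`: a 3D grid of fitted
element-line XRF intensities, one frame per incident energy, acquired by
rastering a nano-focused beam across the sample at each energy across an
absorption edge.  Everything downstream — alignment, decomposition,
linear-combination fitting — consumes and produces these stacks, 1D
:class:`Spectrum` objects, 2D :class:`ElementMap` grids and boolean
:class:`BinaryMask` selections.

Also provided here: the row-major stack<->matrix reshaping used by the
matrix-factorization stage, masked mean-spectrum extraction, an additive
RGB composite renderer, and the detector escape-peak energy predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("specstack")

__all__ = [
    "EnergyStack",
    "Spectrum",
    "ReferenceLibrary",
    "ElementMap",
    "BinaryMask",
    "reshape_to_matrix",
    "reshape_from_matrix",
    "mask_mean_spectrum",
    "escape_peak_energy",
    "rgb_composite",
    "KALPHA_KEV",
    "K_EDGE_KEV",
]

# K-alpha emission and K-edge absorption energies (keV) for the detector
# materials and common lines this package needs.  A tiny built-in table is
# used instead of an external X-ray database; values can be overridden per
# call in escape_peak_energy.
KALPHA_KEV: dict[str, float] = {
    "Si": 1.740,
    "Fe": 6.404,
    "Cu": 8.046,
    "Ge": 9.886,
}
K_EDGE_KEV: dict[str, float] = {
    "Si": 1.839,
    "Fe": 7.112,
    "Cu": 8.979,
    "Ge": 11.103,
}


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_energies(energies: np.ndarray) -> None:
    if energies.ndim != 1:
        raise ValueError("energies must be one-dimensional")
    if energies.size >= 2 and not np.all(np.diff(energies) > 0):
        raise ValueError("energies must be strictly increasing")


@dataclass
class Spectrum:
    """A 1D energy/intensity pair, e.g. a XANES trace or a reference standard.

    ``normalized`` marks spectra brought to unit edge step (pre-edge removed,
    post-edge level ~1); fitting routines require it for references.
    """

    energies: np.ndarray
    intensities: np.ndarray
    name: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.energies = _as_float_array(self.energies, "energies")
        self.intensities = _as_float_array(self.intensities, "intensities")
        _check_energies(self.energies)
        if self.energies.shape != self.intensities.shape:
            raise ValueError(
                f"energies ({self.energies.size}) and intensities "
                f"({self.intensities.size}) differ in length"
            )

    def __len__(self) -> int:
        return self.energies.size

    def copy(self, **replace) -> "Spectrum":
        kw = dict(
            energies=self.energies.copy(),
            intensities=self.intensities.copy(),
            name=self.name,
            normalized=self.normalized,
        )
        kw.update(replace)
        return Spectrum(**kw)


@dataclass
class EnergyStack:
    """3D grid (energy × Y × X) of non-negative element-line intensities.

    Parameters
    ----------
    energies : array (E,)
        Incident beam energies in keV, strictly increasing.
    data : array (E, Y, X)
        Fitted XRF line intensity of ``element`` at each pixel and energy.
    element : str
        Element symbol whose emission line the stack integrates.
    pixel_size : float, optional
        Pixel pitch in nm.
    provenance : list of str
        Log of operations applied to this stack.
    normalized : bool
        True once the stack has been edge-step normalized; normalized stacks
        may contain small negative values (floored downstream), raw count
        stacks must be non-negative.
    """

    energies: np.ndarray
    data: np.ndarray
    element: str = "Fe"
    pixel_size: float | None = None
    provenance: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        self.energies = _as_float_array(self.energies, "energies")
        _check_energies(self.energies)
        self.data = _as_float_array(self.data, "data")
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (E, Y, X), got shape {self.data.shape}")
        if self.data.shape[0] != self.energies.size:
            raise ValueError(
                f"energy axis length {self.energies.size} does not match "
                f"data frames {self.data.shape[0]}"
            )
        if self.data.shape[1] < 1 or self.data.shape[2] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        if not self.normalized and np.any(self.data < 0):
            raise ValueError(
                "raw stack contains negative intensities; clip to zero or "
                "mark the stack normalized"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def n_energies(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1] * self.data.shape[2]

    def log(self, message: str) -> None:
        self.provenance.append(message)
        logger.info("%s: %s", self.element, message)

    def replace(self, **kw) -> "EnergyStack":
        base = dict(
            energies=self.energies.copy(),
            data=self.data.copy(),
            element=self.element,
            pixel_size=self.pixel_size,
            provenance=list(self.provenance),
            normalized=self.normalized,
        )
        base.update(kw)
        return EnergyStack(**base)

    def mean_spectrum(self, name: str = "mean") -> Spectrum:
        """Spectrum of the spatial mean at each energy."""
        return Spectrum(
            self.energies.copy(),
            self.data.mean(axis=(1, 2)),
            name=name,
            normalized=self.normalized,
        )

    def pixel_sums(self) -> np.ndarray:
        """Per-pixel total intensity summed over energies (Y × X)."""
        return self.data.sum(axis=0)


@dataclass
class ElementMap:
    """A 2D abundance map of one element (counts or areal density)."""

    data: np.ndarray
    element: str = ""
    units: str = "counts"

    def __post_init__(self):
        self.data = _as_float_array(self.data, "data")
        if self.data.ndim != 2:
            raise ValueError(f"element map must be 2D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("element map contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean pixel selection over a 2D field."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_selected(self) -> int:
        return int(self.data.sum())


class ReferenceLibrary:
    """Ordered, uniquely named collection of normalized reference spectra.

    The library is the fitting vocabulary for linear-combination analysis:
    each entry is a XANES standard of a known chemical phase, normalized to
    unit edge step so coefficients are comparable across references.
    """

    def __init__(self, entries: Mapping[str, Spectrum] | Iterable[Spectrum], metadata: str = ""):
        if isinstance(entries, Mapping):
            items = list(entries.items())
        else:
            items = [(s.name, s) for s in entries]
        if not items:
            raise ValueError("reference library needs at least one entry")
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate reference name(s): {', '.join(dupes)}")
        self.entries: dict[str, Spectrum] = {}
        for name, spec in items:
            if not spec.normalized:
                raise ValueError(f"reference '{name}' is not normalized")
            self.entries[name] = spec.copy(name=name)
        self.metadata = metadata

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __getitem__(self, name: str) -> Spectrum:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    @property
    def names(self) -> list[str]:
        return list(self.entries.keys())

    def subset(self, names: Sequence[str]) -> "ReferenceLibrary":
        return ReferenceLibrary({n: self.entries[n] for n in names}, metadata=self.metadata)


# ---------------------------------------------------------------------------
# Reshaping between stack (E × Y × X) and matrix (E × P) layouts
# ---------------------------------------------------------------------------

def reshape_to_matrix(stack: EnergyStack) -> np.ndarray:
    """Flatten a stack to the E × P matrix consumed by matrix factorization.

    Pixels are ordered row-major over (Y, X): column ``j`` is the spectrum of
    pixel ``(j // X, j % X)``.  A 73 × 160 × 160 stack becomes 73 × 25600.
    """
    E = stack.n_energies
    return stack.data.reshape(E, stack.n_pixels)


def reshape_from_matrix(matrix: np.ndarray, spatial_shape: tuple[int, int]) -> np.ndarray:
    """Fold a k × P matrix back to a k × Y × X grid (row-major inverse)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"expected 2D matrix, got shape {matrix.shape}")
    ny, nx = spatial_shape
    if matrix.shape[1] != ny * nx:
        raise ValueError(
            f"matrix with {matrix.shape[1]} columns cannot fold to spatial "
            f"shape {spatial_shape} ({ny * nx} pixels)"
        )
    return matrix.reshape(matrix.shape[0], ny, nx)


def mask_mean_spectrum(stack: EnergyStack, mask: BinaryMask) -> Spectrum:
    """Mean spectrum over the pixels a mask selects.

    Used to pull a region-of-interest XANES trace out of a stack, e.g. after
    back-projecting an elemental-correlation selection.
    """
    if mask.shape != stack.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack spatial shape "
            f"{stack.spatial_shape}"
        )
    if mask.n_selected == 0:
        raise ValueError("mask selects no pixels")
    sel = stack.data[:, mask.data]
    return Spectrum(
        stack.energies.copy(),
        sel.mean(axis=1),
        name=f"mean[{mask.label or 'mask'}]",
        normalized=stack.normalized,
    )


def escape_peak_energy(
    line_energy: float,
    detector: str = "Si",
    kalpha_table: Mapping[str, float] | None = None,
    k_edge_table: Mapping[str, float] | None = None,
) -> float | None:
    """Predicted escape-peak energy for a fluorescence line on a detector.

    When an incoming photon above the detector material's K edge is absorbed,
    the detector's own K-alpha fluorescence can escape the sensitive volume,
    leaving a spurious peak at ``line_energy - Kalpha(detector)``.  For the
    Fe K-alpha line (6.404 keV) on a silicon drift detector this predicts
    6.404 - 1.740 = 4.66 keV.

    Returns ``None`` when the line is below the detector K edge (no escape
    possible).  Raises for unknown detector symbols.
    """
    if line_energy <= 0:
        raise ValueError("line energy must be positive (keV)")
    kalpha = dict(KALPHA_KEV)
    kedge = dict(K_EDGE_KEV)
    if kalpha_table:
        kalpha.update(kalpha_table)
    if k_edge_table:
        kedge.update(k_edge_table)
    if detector not in kalpha or detector not in kedge:
        raise KeyError(f"unknown detector element '{detector}'")
    if line_energy <= kedge[detector]:
        return None
    return line_energy - kalpha[detector]


_NAMED_COLORS = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
    "white": (1.0, 1.0, 1.0),
}


def rgb_composite(
    maps: Sequence[ElementMap | np.ndarray],
    colors: Sequence[str | tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Additive color overlay of 2-4 maps, each max-scaled independently.

    Each map is rescaled to [0, 1] by its own maximum (an all-zero map stays
    zero), multiplied by its color and summed; channels are clipped at 1.
    Returns a Y × X × 3 float image.
    """
    if not 1 <= len(maps) <= 4:
        raise ValueError("composite takes 1-4 maps")
    arrays = [m.data if isinstance(m, ElementMap) else np.asarray(m, dtype=float) for m in maps]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"map shapes differ: {shape} vs {a.shape}")
    if colors is None:
        colors = ["red", "green", "blue", "magenta"][: len(arrays)]
    if len(colors) != len(arrays):
        raise ValueError("need one color per map")
    rgb = np.zeros(shape + (3,), dtype=float)
    for a, c in zip(arrays, colors):
        col = np.asarray(_NAMED_COLORS[c] if isinstance(c, str) else c, dtype=float)
        peak = a.max()
        scaled = a / peak if peak > 0 else a
        rgb += scaled[..., None] * col[None, None, :]
    return np.clip(rgb, 0.0, 1.0)
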