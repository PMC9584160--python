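"""Readers and writers for stacks, reference spectra, maps and masks.

On-disk conventions:

* **Energy stack**: a single HDF5 file with datasets ``data`` (E × Y × X,
  float32), ``energies`` (E, float64, keV) and root attributes ``element``,
  ``pixel_size_nm``, ``normalized`` and ``provenance``.  This is a minimal
  self-describing layout, not any beamline schema; TIFF import (below)
  covers data coming from elsewhere.
* **TIFF import**: a directory of single-frame TIFFs (sorted by filename)
  or one multipage TIFF, plus a sidecar text file of incident energies, one
  keV value per line.  Frames are reordered by energy, not filename.
* **Reference spectra**: two-column numeric text/CSV (energy, intensity);
  ``#``-prefixed header lines are skipped, and whitespace-delimited
  Athena-style ``.nor`` exports parse the same way.  Entries are keyed by
  file stem.
* Energies are keV internally; columns that look like eV (values > 1000)
  are converted with a logged warning.

All writers round-trip exactly at 32-bit float precision for image data.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import preprocess
from .core import BinaryMask, ElementMap, EnergyStack, ReferenceLibrary, Spectrum

logger = logging.getLogger("specstack")

__all__ = [
    "load_stack",
    "save_stack",
    "load_references",
    "load_spectrum",
    "export_maps",
    "save_mask_png",
]

EV_THRESHOLD = 1000.0  # energies above this are assumed eV and converted


def _maybe_ev_to_kev(energies: np.ndarray, source: str) -> np.ndarray:
    if energies.size and np.nanmax(np.abs(energies)) > EV_THRESHOLD:
        logger.warning("%s: energies look like eV; converting to keV", source)
        return energies / 1000.0
    return energies


# ---------------------------------------------------------------------------
# Energy stacks
# ---------------------------------------------------------------------------

def save_stack(stack: EnergyStack, path: str | Path) -> Path:
    """Write a stack to the HDF5 container layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=stack.data.astype(np.float32))
        f.create_dataset("energies", data=stack.energies.astype(np.float64))
        f.attrs["element"] = stack.element
        f.attrs["normalized"] = bool(stack.normalized)
        if stack.pixel_size is not None:
            f.attrs["pixel_size_nm"] = float(stack.pixel_size)
        f.attrs["provenance"] = "\n".join(stack.provenance)
    return path


def _load_hdf5(path: Path) -> EnergyStack:
    with h5py.File(path, "r") as f:
        if "energies" not in f:
            raise ValueError(f"{path}: missing 'energies' dataset")
        if "data" not in f:
            raise ValueError(f"{path}: missing 'data' dataset")
        data = np.asarray(f["data"], dtype=float)
        energies = np.asarray(f["energies"], dtype=float)
        element = str(f.attrs.get("element", "Fe"))
        normalized = bool(f.attrs.get("normalized", False))
        pixel_size = f.attrs.get("pixel_size_nm")
        prov = str(f.attrs.get("provenance", ""))
    provenance = [p for p in prov.split("\n") if p]
    return _assemble_stack(
        energies, data, element, provenance, str(path),
        pixel_size=float(pixel_size) if pixel_size is not None else None,
        normalized=normalized,
    )


def _assemble_stack(
    energies, data, element, provenance, source,
    pixel_size=None, normalized=False,
) -> EnergyStack:
    energies = _maybe_ev_to_kev(np.asarray(energies, dtype=float), source)
    if data.shape[0] != energies.size:
        raise ValueError(
            f"{source}: {energies.size} energies but {data.shape[0]} frames"
        )
    order = np.argsort(energies)
    if not np.array_equal(order, np.arange(energies.size)):
        logger.info("%s: reordering frames into ascending energy", source)
        energies, data = energies[order], data[order]
    if not normalized:
        n_neg = int((data < 0).sum())
        if n_neg:
            logger.warning("%s: clipped %d negative intensities to 0", source, n_neg)
            data = np.clip(data, 0.0, None)
    return EnergyStack(
        energies, data, element=element, pixel_size=pixel_size,
        provenance=provenance + [f"loaded from {source}"], normalized=normalized,
    )


def _load_tiff_series(path: Path, energies_path: Path | None, element: str) -> EnergyStack:
    if path.is_dir():
        frames_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not frames_files:
            raise ValueError(f"{path}: no TIFF files found")
        data = np.stack([tifffile.imread(p) for p in frames_files]).astype(float)
        if energies_path is None:
            candidate = path / "energies.txt"
            if not candidate.exists():
                raise ValueError(
                    f"{path}: no energies sidecar given and {candidate} absent"
                )
            energies_path = candidate
    else:
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        if energies_path is None:
            raise ValueError(f"{path}: multipage TIFF needs an energies sidecar file")
    energies = np.loadtxt(energies_path, ndmin=1)
    return _assemble_stack(energies, data, element, [], str(path))


def load_stack(
    path: str | Path,
    format: str = "auto",
    energies_path: str | Path | None = None,
    element: str = "Fe",
) -> EnergyStack:
    """Load an energy stack from HDF5 or a TIFF series + energy sidecar."""
    path = Path(path)
    if format == "auto":
        if path.is_dir() or path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff_series"
        else:
            format = "hdf5"
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "tiff_series":
        return _load_tiff_series(
            path, Path(energies_path) if energies_path else None, element
        )
    raise ValueError(f"unknown format '{format}'")


# ---------------------------------------------------------------------------
# Reference spectra
# ---------------------------------------------------------------------------

def _read_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        arr = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two numeric columns")
    return arr[:, 0], arr[:, 1]


def load_spectrum(path: str | Path, name: str | None = None) -> Spectrum:
    """Read one two-column spectrum file; flag it normalized if the
    post-edge level (mean over the top quartile of the energy range) sits
    in [0.8, 1.2]."""
    path = Path(path)
    energies, intensities = _read_two_column(path)
    if energies.size < 10:
        raise ValueError(f"{path}: fewer than 10 points")
    energies = _maybe_ev_to_kev(energies, str(path))
    if not np.all(np.diff(energies) > 0):
        raise ValueError(f"{path}: energies not strictly increasing")
    post = energies >= energies[0] + 0.75 * (energies[-1] - energies[0])
    post_mean = float(intensities[post].mean())
    return Spectrum(
        energies,
        intensities,
        name=name or path.stem,
        normalized=0.8 <= post_mean <= 1.2,
    )


def load_references(
    paths: str | Path | Iterable[str | Path],
    auto_normalize: bool = True,
) -> ReferenceLibrary:
    """Build a reference library from spectrum files or a directory of them.

    Files not already normalized (post-edge level outside [0.8, 1.2]) are
    edge-step normalized on load when ``auto_normalize`` (logged); with
    ``auto_normalize=False`` such files are an error, since the library
    contract requires normalized entries.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        root = Path(paths)
        files = sorted(
            p
            for p in root.iterdir()
            if p.suffix.lower() in (".csv", ".txt", ".dat", ".nor", ".xmu")
        )
    elif isinstance(paths, (str, Path)):
        files = [Path(paths)]
    else:
        files = [Path(p) for p in paths]
    if not files:
        raise ValueError("no reference files found")
    stems = [f.stem for f in files]
    dupes = sorted({s for s in stems if stems.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate reference name(s): {', '.join(dupes)}")
    entries: dict[str, Spectrum] = {}
    for f in files:
        spec = load_spectrum(f)
        if not spec.normalized:
            if not auto_normalize:
                raise ValueError(f"{f}: spectrum is not normalized")
            logger.info("%s: normalizing raw reference on load", f)
            spec, _ = preprocess.normalize_spectrum(spec)
        entries[spec.name] = spec
    return ReferenceLibrary(entries, metadata=f"loaded from {len(files)} file(s)")


# ---------------------------------------------------------------------------
# Maps and masks
# ---------------------------------------------------------------------------

def export_maps(
    maps: Mapping[str, ElementMap | np.ndarray],
    path_prefix: str | Path,
) -> pd.DataFrame:
    """Write one float32 TIFF per map plus a CSV summary.

    The summary holds per-map sum, mean, max and the map's share of the
    total weight across the set (the spectral fraction when the maps are
    LCF coefficient maps).  Returns the summary frame.
    """
    if not maps:
        raise ValueError("empty map set")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        name: (m.data if isinstance(m, ElementMap) else np.asarray(m, dtype=float))
        for name, m in maps.items()
    }
    total = sum(a.sum() for a in arrays.values())
    records = []
    for name, a in arrays.items():
        tifffile.imwrite(f"{prefix}_{name}.tif", a.astype(np.float32))
        records.append(
            {
                "name": name,
                "sum": a.sum(),
                "mean": a.mean(),
                "max": a.max(),
                "fraction": a.sum() / total if total > 0 else 0.0,
            }
        )
    summary = pd.DataFrame(records)
    summary.to_csv(f"{prefix}_summary.csv", index=False)
    return summary


def save_mask_png(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG preview (255 = selected)."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (mask.data.astype(np.uint8) * 255))
    return path
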