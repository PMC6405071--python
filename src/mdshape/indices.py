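"""Broadband and narrow-band comparison indices (NDVI, EVI, NDII, NRI, PSRI, PRI).

Broadband inputs are unweighted means over fixed wavelength ranges —
NIR 750-850 nm, red 600-700 nm, green 500-600 nm, blue 400-500 nm — so the
same ranges apply regardless of a sensor's band layout.  NDII and PRI use
single narrow bands picked as the nearest retained band to their nominal
wavelengths (819/1649 nm and 529/580 nm respectively; wavelength ties break
toward the shorter band).

Formulas (as used in the classification experiments):

    NDVI = (Red - NIR) / (Red + NIR)
    EVI  = 2.5 (NIR - Red) / (1 + NIR + 6 Red - 7.5 Blue)
    NDII = (R819 - R1649) / (R819 + R1649)
    NRI  = (Green - Red) / (Green + Red)
    PSRI = (Red - Blue) / NIR
    PRI  = (R529 - R580) / (R529 + R580)

Note the NDVI orientation: the red band leads the numerator, the reverse of
the common (NIR - Red)/(NIR + Red).  Tree-based classifiers are invariant
to the sign flip, so either orientation yields the same pipeline behaviour;
``standard_orientation=True`` selects the conventional form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureStack, HyperCube

__all__ = [
    "BandRanges",
    "INDEX_NAMES",
    "broadband_average",
    "compute_index",
    "index_stack",
]

INDEX_NAMES = ("NDVI", "EVI", "NDII", "NRI", "PSRI", "PRI")

#: Nominal narrow-band wavelengths (nm) per index.
NARROW_BANDS = {"NDII": (819.0, 1649.0), "PRI": (529.0, 580.0)}


@dataclass(frozen=True)
class BandRanges:
    """Broadband wavelength windows (nm), inclusive at both ends."""

    nir: tuple[float, float] = (750.0, 850.0)
    red: tuple[float, float] = (600.0, 700.0)
    green: tuple[float, float] = (500.0, 600.0)
    blue: tuple[float, float] = (400.0, 500.0)


def broadband_average(cube: HyperCube, range_nm: tuple[float, float]) -> np.ndarray:
    """Per-pixel unweighted mean reflectance over all retained bands in a range."""
    lo, hi = range_nm
    wl = cube.retained_wavelengths
    sel = (wl >= lo) & (wl <= hi)
    if not sel.any():
        raise ValueError(
            f"no retained band in [{lo}, {hi}] nm; available wavelengths span "
            f"{wl[0]:.1f}-{wl[-1]:.1f} nm ({wl.size} bands)"
        )
    return cube.retained[sel].mean(axis=0)


def _narrow_band(cube: HyperCube, target_nm: float, index: str) -> np.ndarray:
    wl = cube.retained_wavelengths
    if target_nm < wl[0] or target_nm > wl[-1]:
        raise ValueError(
            f"{index} needs a band near {target_nm:.0f} nm, outside the cube's "
            f"wavelength coverage {wl[0]:.1f}-{wl[-1]:.1f} nm"
        )
    return cube.retained[cube.nearest_band(target_nm)]


def _norm_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def compute_index(
    cube: HyperCube,
    name: str,
    ranges: BandRanges | None = None,
    standard_orientation: bool = False,
) -> np.ndarray:
    """One spectral index as a ``(rows, cols)`` raster.

    ``standard_orientation`` flips NDVI to (NIR - Red)/(NIR + Red); all
    other indices are unaffected.  Zero denominators yield NaN.
    """
    name = name.upper()
    if name not in INDEX_NAMES:
        raise ValueError(f"unknown index {name!r}; choose from {INDEX_NAMES}")
    ranges = ranges or BandRanges()

    if name == "NDVI":
        red = broadband_average(cube, ranges.red)
        nir = broadband_average(cube, ranges.nir)
        return _norm_diff(nir, red) if standard_orientation else _norm_diff(red, nir)
    if name == "EVI":
        nir = broadband_average(cube, ranges.nir)
        red = broadband_average(cube, ranges.red)
        blue = broadband_average(cube, ranges.blue)
        denom = 1.0 + nir + 6.0 * red - 7.5 * blue
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom != 0, 2.5 * (nir - red) / denom, np.nan)
    if name == "NDII":
        lo, hi = NARROW_BANDS["NDII"]
        return _norm_diff(_narrow_band(cube, lo, name), _narrow_band(cube, hi, name))
    if name == "NRI":
        green = broadband_average(cube, ranges.green)
        red = broadband_average(cube, ranges.red)
        return _norm_diff(green, red)
    if name == "PSRI":
        red = broadband_average(cube, ranges.red)
        blue = broadband_average(cube, ranges.blue)
        nir = broadband_average(cube, ranges.nir)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(nir != 0, (red - blue) / nir, np.nan)
    # PRI
    lo, hi = NARROW_BANDS["PRI"]
    return _norm_diff(_narrow_band(cube, lo, name), _narrow_band(cube, hi, name))


def index_stack(
    cube: HyperCube,
    names: tuple[str, ...] = INDEX_NAMES,
    ranges: BandRanges | None = None,
    standard_orientation: bool = False,
) -> FeatureStack:
    """All requested indices as a named feature stack."""
    stack = FeatureStack(cube.rows, cube.cols)
    for name in names:
        layer = compute_index(cube, name, ranges, standard_orientation)
        stack.add(
            name.upper(),
            layer,
            operation="spectral_index",
            index=name.upper(),
            standard_orientation=standard_orientation,
        )
    return stack
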