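"""Shared in-memory containers for hyperspectral scenes and derived features.

Conventions used throughout the package:

* raster arrays are ``(rows, cols)``; cubes are ``(bands, rows, cols)``;
* band indices and raster row/col indices are 0-based everywhere;
* reflectance is unitless, typically in ``[0, 1]``;
* wavelengths are nanometres and strictly increasing with band index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "SpectralCurve",
    "PivotPair",
    "HyperCube",
    "FeatureStack",
    "SegmentMap",
]


@dataclass(frozen=True)
class SpectralCurve:
    """A single reflectance spectrum with its abscissa positions.

    Parameters
    ----------
    reflectance
        Reflectance values, one per sample (unitless; >= 0 expected).
    abscissa
        Strictly increasing sample positions.  By default these are the
        retained-band ordinal indices ``0, 1, 2, ...``; wavelength-nm
        positions may be supplied instead when curve geometry should be
        measured in nanometres.
    """

    reflectance: np.ndarray
    abscissa: np.ndarray

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance, dtype=float)
        absc = np.asarray(self.abscissa, dtype=float)
        if refl.ndim != 1 or absc.ndim != 1:
            raise ValueError("reflectance and abscissa must be 1-D")
        if refl.shape != absc.shape:
            raise ValueError(
                f"reflectance has {refl.size} samples but abscissa has {absc.size}"
            )
        if refl.size < 1:
            raise ValueError("a spectral curve needs at least one sample")
        if absc.size > 1 and not np.all(np.diff(absc) > 0):
            raise ValueError("abscissa must be strictly increasing")
        object.__setattr__(self, "reflectance", refl)
        object.__setattr__(self, "abscissa", absc)

    @property
    def n(self) -> int:
        return int(self.reflectance.size)

    @classmethod
    def from_reflectance(cls, reflectance: Sequence[float]) -> "SpectralCurve":
        """Curve over ordinal band indices 0..n-1."""
        refl = np.asarray(reflectance, dtype=float)
        return cls(refl, np.arange(refl.size, dtype=float))

    def reversed(self) -> "SpectralCurve":
        """The curve with its reflectance sequence reversed (same abscissa)."""
        return SpectralCurve(self.reflectance[::-1].copy(), self.abscissa.copy())


@dataclass(frozen=True)
class PivotPair:
    """Left/right pivot positions on a curve's abscissa, ``lp <= rp``."""

    lp: float
    rp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lp) or not np.isfinite(self.rp):
            raise ValueError("pivots must be finite")
        if self.lp > self.rp:
            raise ValueError(f"left pivot {self.lp} exceeds right pivot {self.rp}")


class HyperCube:
    """A hyperspectral reflectance cube with wavelengths and a band mask.

    Parameters
    ----------
    data
        Reflectance, shape ``(bands, rows, cols)``.
    wavelengths
        Band-centre wavelengths in nm, strictly increasing, length ``bands``.
    band_mask
        Boolean retained-band flags (True = keep).  Masked (bad) bands are
        excluded from every derived computation; the retained bands are
        re-indexed contiguously (0, 1, 2, ...) for index-unit abscissae.
    meta
        Opaque passthrough metadata (geotransform, CRS string, nodata, ...).
    """

    def __init__(
        self,
        data: np.ndarray,
        wavelengths: Sequence[float],
        band_mask: Sequence[bool] | None = None,
        meta: Mapping[str, object] | None = None,
    ) -> None:
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("cube data must be (bands, rows, cols)")
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size != data.shape[0]:
            raise ValueError(
                f"{wl.size} wavelengths for {data.shape[0]} bands"
            )
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if band_mask is None:
            mask = np.ones(data.shape[0], dtype=bool)
        else:
            mask = np.asarray(band_mask, dtype=bool)
            if mask.shape != (data.shape[0],):
                raise ValueError("band_mask length must equal band count")
        if not mask.any():
            raise ValueError("band_mask retains no bands")
        self.data = data
        self.wavelengths = wl
        self.band_mask = mask
        self.meta: dict[str, object] = dict(meta or {})

    # -- shape helpers -----------------------------------------------------
    @property
    def n_bands(self) -> int:
        return int(self.data.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def rows(self) -> int:
        return int(self.data.shape[1])

    @property
    def cols(self) -> int:
        return int(self.data.shape[2])

    # -- retained-band views ----------------------------------------------
    @property
    def retained(self) -> np.ndarray:
        """Reflectance of retained bands, ``(n_retained, rows, cols)``."""
        return self.data[self.band_mask]

    @property
    def retained_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.band_mask]

    @property
    def n_retained(self) -> int:
        return int(self.band_mask.sum())

    def abscissa(self, units: str = "index") -> np.ndarray:
        """Abscissa positions of the retained bands.

        ``units='index'`` gives the contiguous ordinals 0..m-1 (default);
        ``units='nm'`` gives the retained bands' wavelengths.
        """
        if units == "index":
            return np.arange(self.n_retained, dtype=float)
        if units == "nm":
            return self.retained_wavelengths.astype(float)
        raise ValueError(f"unknown abscissa units {units!r} (use 'index' or 'nm')")

    def pixel_curve(self, row: int, col: int, units: str = "index") -> SpectralCurve:
        return SpectralCurve(self.retained[:, row, col], self.abscissa(units))

    def nearest_band(self, wavelength_nm: float) -> int:
        """Retained-band ordinal of the band nearest a target wavelength.

        Ties between two equally near bands resolve to the shorter
        wavelength.
        """
        wl = self.retained_wavelengths
        dist = np.abs(wl - wavelength_nm)
        return int(np.argmin(dist))  # argmin takes the first (shorter) on ties


class FeatureStack:
    """Named per-pixel feature layers sharing one raster grid.

    Layers are float rasters of a common ``(rows, cols)`` shape, addressed
    by unique name.  A provenance record (operation + parameters) is kept
    per layer.
    """

    def __init__(self, rows: int, cols: int) -> None:
        self.rows = int(rows)
        self.cols = int(cols)
        self._layers: dict[str, np.ndarray] = {}
        self.provenance: dict[str, dict[str, object]] = {}

    def add(self, name: str, layer: np.ndarray, **prov: object) -> None:
        layer = np.asarray(layer, dtype=np.float64)
        if layer.shape != (self.rows, self.cols):
            raise ValueError(
                f"layer {name!r} has shape {layer.shape}, stack is "
                f"({self.rows}, {self.cols})"
            )
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        self._layers[name] = layer
        self.provenance[name] = dict(prov)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def subset(self, names: Sequence[str]) -> "FeatureStack":
        out = FeatureStack(self.rows, self.cols)
        for name in names:
            if name not in self._layers:
                raise KeyError(f"feature layer {name!r} not in stack")
            out.add(name, self._layers[name], **self.provenance[name])
        return out

    def to_array(self) -> np.ndarray:
        """Stack as ``(n_layers, rows, cols)`` in insertion order."""
        return np.stack([self._layers[n] for n in self._layers], axis=0)


@dataclass
class SegmentMap:
    """Integer label raster partitioning a scene into objects.

    Labels are dense ``1..n_segments``; every pixel carries exactly one
    label, and each label's pixels form one connected region.
    """

    labels: np.ndarray
    scale: float
    connectivity: int = 4

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer raster")
        if labels.min() < 1:
            raise ValueError("segment labels must start at 1")
        self.labels = labels

    @property
    def n_segments(self) -> int:
        return int(self.labels.max())
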