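"""Reading and writing cubes and rasters (ENVI header+binary, TIFF, sidecars).

Cubes travel either as ENVI flat binaries with a ``.hdr`` text header
(interleaves BSQ/BIL/BIP, the common hyperspectral distribution format) or
as band-major multi-page TIFFs.  Single-band outputs are float32 TIFFs
with NaN nodata recorded in the GDAL_NODATA tag; geotransform/CRS strings
are passed through opaquely in the ImageDescription tag (this package
never interprets them).

Wavelengths come from the ENVI header's ``wavelength`` field or from a
sidecar CSV with columns ``band,wavelength_nm``.  Integer digital-number
cubes must be given an explicit reflectance scale factor; the reader never
guesses one.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import HyperCube

__all__ = [
    "read_cube",
    "write_cube",
    "read_raster",
    "write_raster",
    "read_wavelength_csv",
    "read_band_mask",
]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

GDAL_NODATA_TAG = 42113


# ---------------------------------------------------------------------------
# sidecars


def read_wavelength_csv(path: str | Path) -> np.ndarray:
    """Wavelengths from a ``band,wavelength_nm`` CSV (header optional)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.replace(";", ",").split(",")
        try:
            rows.append((int(float(parts[0])), float(parts[1])))
        except ValueError:
            continue  # header line
    if not rows:
        raise ValueError(f"no band,wavelength_nm rows found in {path}")
    rows.sort()
    return np.array([w for _, w in rows], dtype=float)


def read_band_mask(path: str | Path) -> np.ndarray:
    """Boolean retained-band flags from a whitespace/newline 0/1 text file."""
    tokens = Path(path).read_text().split()
    return np.array([bool(int(t)) for t in tokens], dtype=bool)


# ---------------------------------------------------------------------------
# ENVI header + binary


def _parse_envi_header(hdr_path: Path) -> dict[str, str]:
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not in_braces:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if value.startswith("{") and not value.endswith("}"):
                in_braces, buf = True, [value.lstrip("{")]
            else:
                fields[key] = value.strip("{} ")
        else:
            if line.endswith("}"):
                buf.append(line.rstrip("}"))
                fields[key] = " ".join(buf)
                in_braces = False
            else:
                buf.append(line)
    return fields


def _find_envi_pair(path: Path) -> tuple[Path, Path]:
    """(header, binary) from either member of an ENVI pair."""
    if path.suffix.lower() == ".hdr":
        hdr = path
        for cand in (path.with_suffix(""), path.with_suffix(".img"),
                     path.with_suffix(".dat"), path.with_suffix(".bil")):
            if cand.exists() and cand != hdr:
                return hdr, cand
        raise FileNotFoundError(f"no binary found next to header {path}")
    for cand in (path.with_suffix(".hdr"), Path(str(path) + ".hdr")):
        if cand.exists():
            return cand, path
    raise FileNotFoundError(f"no ENVI header (.hdr) found for {path}")


def _read_envi(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    hdr_path, bin_path = _find_envi_pair(path)
    hdr = _parse_envi_header(hdr_path)
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(hdr.get("data type", 4))])
    if int(hdr.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = hdr.get("interleave", "bsq").lower()
    raw = np.fromfile(bin_path, dtype=dtype)
    expected = bands * rows * cols
    if raw.size != expected:
        raise ValueError(
            f"{bin_path}: {raw.size} values but header implies {expected} "
            f"({bands} bands x {rows} x {cols})"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(1, 0, 2)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands).transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    wl = None
    if "wavelength" in hdr:
        wl = np.array([float(v) for v in hdr["wavelength"].split(",") if v.strip()])
        if wl.size != bands:
            raise ValueError(
                f"header lists {wl.size} wavelengths for {bands} bands"
            )
    return np.ascontiguousarray(data), wl


def write_cube(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> Path:
    """Write a cube as an ENVI float32 binary + ``.hdr`` header."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError("interleave must be bsq, bil or bip")
    data = cube.data.astype(np.float32)
    if interleave == "bil":
        out = data.transpose(1, 0, 2)
    elif interleave == "bip":
        out = data.transpose(1, 2, 0)
    else:
        out = data
    out.tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    Path(str(path) + ".hdr").write_text(hdr)
    return path


# ---------------------------------------------------------------------------
# cube reader (ENVI or TIFF)


def read_cube(
    path: str | Path,
    wavelengths: str | Path | np.ndarray | None = None,
    band_mask: str | Path | np.ndarray | None = None,
    scale: float | None = None,
) -> HyperCube:
    """Load a hyperspectral cube with its wavelengths and band mask.

    ``wavelengths`` may be an explicit array or a sidecar CSV path; for
    ENVI inputs the header's wavelength field is used when present.
    Integer cubes (digital numbers) require ``scale`` (reflectance =
    DN * scale); the reader refuses to guess.
    """
    path = Path(path)
    wl = None
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"unsupported TIFF layout {data.shape}")
    else:
        data, wl = _read_envi(path)
    if np.issubdtype(data.dtype, np.integer):
        if scale is None:
            raise ValueError(
                "integer digital-number cube: pass an explicit reflectance "
                "scale factor (e.g. scale=1e-4 for AVIRIS-style DN)"
            )
        data = data.astype(np.float64) * scale
    elif scale is not None:
        data = data.astype(np.float64) * scale

    if wavelengths is not None:
        if isinstance(wavelengths, (str, Path)):
            wl = read_wavelength_csv(wavelengths)
        else:
            wl = np.asarray(wavelengths, dtype=float)
    if wl is None:
        raise ValueError(
            f"{path}: no wavelengths in the file; supply a band,wavelength_nm "
            "sidecar CSV via the wavelengths argument"
        )
    if wl.size != data.shape[0]:
        raise ValueError(
            f"{wl.size} wavelengths for a {data.shape[0]}-band cube"
        )
    mask = None
    if band_mask is not None:
        mask = (
            read_band_mask(band_mask)
            if isinstance(band_mask, (str, Path))
            else np.asarray(band_mask, dtype=bool)
        )
    return HyperCube(data, wl, band_mask=mask, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# single-band rasters (TIFF)


def write_raster(
    layer: np.ndarray,
    path: str | Path,
    like: HyperCube | None = None,
    nodata: float = float("nan"),
) -> Path:
    """Write one raster layer as float32 (or int32 for labels) TIFF.

    NaN pixels are the nodata value (GDAL_NODATA tag).  Geotransform/CRS
    strings found in ``like.meta`` are carried verbatim in the
    ImageDescription tag.
    """
    path = Path(path)
    layer = np.asarray(layer)
    if layer.ndim != 2:
        raise ValueError("write_raster expects a single 2-D layer")
    if like is not None and layer.shape != (like.rows, like.cols):
        raise ValueError(
            f"layer shape {layer.shape} does not match reference cube "
            f"({like.rows}, {like.cols})"
        )
    if np.issubdtype(layer.dtype, np.integer):
        out = layer.astype(np.int32)
        nodata_str = "0"
    else:
        out = layer.astype(np.float32)
        nodata_str = "nan" if np.isnan(nodata) else repr(float(nodata))
    meta = {}
    if like is not None:
        for key in ("geotransform", "crs", "source"):
            if key in like.meta:
                meta[key] = like.meta[key]
    tifffile.imwrite(
        path,
        out,
        description=json.dumps(meta),
        extratags=[(GDAL_NODATA_TAG, "s", 0, nodata_str, True)],
    )
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict[str, object]]:
    """Read a single-band TIFF back: ``(array, metadata)``."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        meta: dict[str, object] = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {"description": desc.value}
        nod = page.tags.get(GDAL_NODATA_TAG)
        if nod is not None:
            meta["nodata"] = nod.value
    return arr, meta
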