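"""Seeded synthetic hyperspectral scenes with shape-confusable class pairs.

Real hyperspectral benchmarks are multi-hundred-megabyte downloads, so the
test scenes here are generated: labeled patchworks of field-like regions,
each carrying a class reflectance template plus per-band Gaussian noise.

The scientifically interesting ingredient is the *confusable pair*: two
classes whose broadband means (NIR/red/green/blue) are identical to within
1e-6 — so every broadband index (NDVI, EVI, NRI, PSRI) sees them as the
same class — but whose fine spectral structure differs through a narrow
absorption dip balanced by a small uniform offset inside the same
broadband window.  This emulates tillage-style class pairs (e.g. no-till
vs minimum-till fields) that defeat broadband indices while remaining
separable to whole-curve shape metrics such as MDRRL.

Templates are piecewise-linear qualitative stand-ins (green peak ~550 nm,
red trough ~670 nm, red-edge rise, NIR plateau, SWIR decline), not
radiative-transfer output: the tests need shape control, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import HyperCube
from .indices import BandRanges

__all__ = [
    "ClassSpec",
    "SceneSpec",
    "vegetation_template",
    "soil_template",
    "make_confusable_pair",
    "default_classes",
    "make_scene",
]

DEFAULT_DIP = (450.0, 80.0, 0.15)  # centre nm, full width nm, depth


def vegetation_template() -> tuple[tuple[float, float], ...]:
    """Piecewise-linear green-vegetation reflectance knots (nm, reflectance)."""
    return (
        (400.0, 0.04), (490.0, 0.06), (550.0, 0.12), (620.0, 0.09),
        (670.0, 0.05), (700.0, 0.10), (740.0, 0.34), (780.0, 0.44),
        (900.0, 0.46), (970.0, 0.42), (1100.0, 0.45), (1250.0, 0.40),
        (1450.0, 0.22), (1650.0, 0.26), (1700.0, 0.25),
    )


def soil_template() -> tuple[tuple[float, float], ...]:
    """Bright soil / crop-residue mixture: slowly rising, featureless."""
    return (
        (400.0, 0.16), (500.0, 0.18), (600.0, 0.20), (700.0, 0.22),
        (900.0, 0.28), (1100.0, 0.32), (1400.0, 0.30), (1700.0, 0.34),
    )


@dataclass(frozen=True)
class ClassSpec:
    """One class's reflectance model.

    ``base`` are piecewise-linear knots; ``amplitude`` scales the whole
    curve; ``absorption`` features are compact quadratic dips
    ``(centre nm, full width nm, depth)``; ``offsets`` are rectangular
    additive shifts ``(lo nm, hi nm, value)`` (used to rebalance broadband
    means).  Evaluated reflectance must stay inside [0, 1].
    """

    name: str
    base: tuple[tuple[float, float], ...]
    amplitude: float = 1.0
    absorption: tuple[tuple[float, float, float], ...] = ()
    offsets: tuple[tuple[float, float, float], ...] = ()

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        knots = np.asarray(self.base, dtype=float)
        rho = self.amplitude * np.interp(wl, knots[:, 0], knots[:, 1])
        for centre, width, depth in self.absorption:
            u = 2.0 * (wl - centre) / width
            rho = rho - depth * np.clip(1.0 - u**2, 0.0, None)
        for lo, hi, value in self.offsets:
            rho = rho + np.where((wl >= lo) & (wl <= hi), value, 0.0)
        if (rho < 0).any() or (rho > 1).any():
            raise ValueError(
                f"class {self.name!r}: reflectance leaves [0, 1] "
                f"(range {rho.min():.3f}..{rho.max():.3f})"
            )
        return rho


def make_confusable_pair(
    template: ClassSpec,
    dip: tuple[float, float, float] = DEFAULT_DIP,
    ranges: BandRanges | None = None,
    wavelengths: np.ndarray | None = None,
) -> tuple[ClassSpec, ClassSpec]:
    """Split one template into two classes with matched broadband means.

    Class B is class A plus an absorption dip, plus a uniform compensating
    offset over the broadband range containing the dip, sized (on the
    actual band grid) so that A and B have identical means over all four
    broadband ranges.  Consequently every broadband index agrees between
    the classes while whole-curve shape metrics do not.
    """
    ranges = ranges or BandRanges()
    if wavelengths is None:
        wavelengths = default_wavelengths()
    wl = np.asarray(wavelengths, dtype=float)
    centre, width, depth = dip
    containing = None
    for rng_name in ("nir", "red", "green", "blue"):
        lo, hi = getattr(ranges, rng_name)
        if lo <= centre - width / 2 and centre + width / 2 <= hi:
            containing = (lo, hi)
            break
    if containing is None:
        raise ValueError(
            f"dip {centre}+/-{width / 2} nm is not fully inside any broadband range"
        )
    lo, hi = containing
    in_range = (wl >= lo) & (wl <= hi)
    if not in_range.any():
        raise ValueError(f"no band falls inside the dip's range [{lo}, {hi}] nm")
    u = 2.0 * (wl - centre) / width
    dip_profile = depth * np.clip(1.0 - u**2, 0.0, None)
    delta = float(dip_profile[in_range].mean())
    a = replace(template, name=f"{template.name}_a")
    b = replace(
        template,
        name=f"{template.name}_b",
        absorption=template.absorption + ((centre, width, depth),),
        offsets=template.offsets + ((lo, hi, delta),),
    )
    b.spectrum(wl)  # validate: compensation must not leave [0, 1]
    return a, b


def default_wavelengths(n_bands: int = 100, wl_range: tuple[float, float] = (400.0, 1700.0)) -> np.ndarray:
    return np.linspace(wl_range[0], wl_range[1], n_bands)


def default_classes(wavelengths: np.ndarray | None = None) -> tuple[ClassSpec, ...]:
    """Four classes: two kinds of vegetation plus a confusable soil pair."""
    if wavelengths is None:
        wavelengths = default_wavelengths()
    veg = ClassSpec("vegetation", vegetation_template())
    sparse = ClassSpec("sparse_vegetation", vegetation_template(), amplitude=0.7)
    tillage_a, tillage_b = make_confusable_pair(
        ClassSpec("tillage", soil_template()), DEFAULT_DIP, wavelengths=wavelengths
    )
    return (veg, sparse, tillage_a, tillage_b)


@dataclass
class SceneSpec:
    """Synthetic scene parameters.

    The default fixture is a 64x64 scene of 100 bands spanning
    400-1700 nm (so the NDII and PRI narrow bands both exist), a 10x10
    patchwork of fields with jittered borders, four classes of which two
    are a confusable pair, and per-band Gaussian noise of sd 0.01.
    """

    rows: int = 64
    cols: int = 64
    n_bands: int = 100
    wl_range: tuple[float, float] = (400.0, 1700.0)
    classes: tuple[ClassSpec, ...] | None = None
    fields: tuple[int, int] = (10, 10)
    border_jitter: int = 2
    noise_sd: float = 0.01
    #: sd of the per-pixel multiplicative brightness factor (illumination /
    #: moisture variability).  Scale-invariant index ratios are immune to
    #: it, but it dominates the scene's principal components, as brightness
    #: does in real imagery.
    brightness_sd: float = 0.05
    seed: int = 0

    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.n_bands, self.wl_range)


def _jittered_cuts(n_pix: int, n_fields: int, n_lines: int, jitter: int, rng) -> np.ndarray:
    """Cut positions per transverse line: (n_fields - 1, n_lines)."""
    base = np.round(np.arange(1, n_fields) * n_pix / n_fields).astype(int)
    cuts = np.empty((n_fields - 1, n_lines), dtype=int)
    for i, b in enumerate(base):
        walk = rng.integers(-1, 2, size=n_lines).cumsum()
        walk = np.clip(walk, -jitter, jitter)
        cuts[i] = np.clip(b + walk, 1, n_pix - 1)
    return cuts


def make_scene(spec: SceneSpec | None = None) -> tuple[HyperCube, np.ndarray]:
    """Generate a labeled synthetic scene.

    Returns ``(cube, truth)``: the noisy reflectance cube and an aligned
    integer truth raster (classes 1..C covering every pixel).  Deterministic
    under ``spec.seed``.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths()
    classes = spec.classes if spec.classes is not None else default_classes(wl)
    if len(classes) < 2:
        raise ValueError("a scene needs at least 2 classes")
    spectra = np.stack([c.spectrum(wl) for c in classes])  # (C, bands)

    ny, nx = spec.fields
    row_cuts = _jittered_cuts(spec.rows, ny, spec.cols, spec.border_jitter, rng)
    col_cuts = _jittered_cuts(spec.cols, nx, spec.rows, spec.border_jitter, rng)
    rr = np.arange(spec.rows)[:, None]
    cc = np.arange(spec.cols)[None, :]
    # row_cuts is (ny-1, cols): compare each pixel's row against its column's cuts
    field_row = np.zeros((spec.rows, spec.cols), dtype=int)
    for i in range(ny - 1):
        field_row += rr >= row_cuts[i][None, :]
    field_col = np.zeros((spec.rows, spec.cols), dtype=int)
    for i in range(nx - 1):
        field_col += cc >= col_cuts[i][:, None]
    field_id = field_row * nx + field_col

    n_fields = ny * nx
    reps = int(np.ceil(n_fields / len(classes)))
    assignment = np.tile(np.arange(len(classes)), reps)[:n_fields]
    rng.shuffle(assignment)
    truth = (assignment[field_id] + 1).astype(np.int64)

    cube_data = spectra[truth - 1].transpose(2, 0, 1)  # (bands, rows, cols)
    if spec.brightness_sd > 0:
        gain = 1.0 + rng.normal(0.0, spec.brightness_sd, size=(spec.rows, spec.cols))
        cube_data = cube_data * np.clip(gain, 0.5, 1.5)[None, :, :]
    if spec.noise_sd > 0:
        cube_data = cube_data + rng.normal(
            0.0, spec.noise_sd, size=cube_data.shape
        )
        cube_data = np.clip(cube_data, 0.0, 1.0)
    cube = HyperCube(
        cube_data,
        wl,
        meta={"source": "mdshape.synthetic", "noise_sd": spec.noise_sd, "seed": spec.seed},
    )
    return cube, truth
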