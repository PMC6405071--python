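"""Moment-distance shape metrics for spectral reflectance curves.

The moment distance of a curve from a *pivot* is the sum, over every band
in a pivot-bounded window, of the hypotenuse from the pivot's abscissa
position to the point ``(x_i, rho_i)``:

    MD_LP = sum_i sqrt(rho_i^2 + (x_i - lp)^2)       (left pivot)
    MD_RP = sum_i sqrt(rho_i^2 + (rp - x_i)^2)       (right pivot)

Because every hypotenuse touches every band, the pair (MD_LP, MD_RP)
responds to the *whole shape* of the curve — including narrow absorption
features that broadband averages wash out.  Four scalar summaries are
derived from the pair:

    MDI   = MD_RP - MD_LP          (unbounded difference)
    MDIN  = MDI / (MD_RP + MD_LP)  (normalized; in (-1, 1) for positive curves)
    MDRLR = MD_LP / MD_RP          (left/right ratio)
    MDRRL = MD_RP / MD_LP          (right/left ratio; MDRLR * MDRRL = 1)

MDI grows with band count, which hampers cross-sensor comparison; MDIN and
the two ratios are the bounded/normalized alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .containers import HyperCube, PivotPair, SpectralCurve

__all__ = [
    "MDMetric",
    "MDResult",
    "moment_distance_lp",
    "moment_distance_rp",
    "md_metrics",
    "md_cube",
    "md_sweep",
]


class MDMetric(str, Enum):
    """Selectable scalar member of the moment-distance family."""

    MDI = "mdi"
    MDIN = "mdin"
    MDRLR = "mdrlr"
    MDRRL = "mdrrl"


@dataclass(frozen=True)
class MDResult:
    """All six moment-distance quantities for one curve/window.

    ``n_used`` is the number of samples that entered the sums (relevant
    when NaN samples were skipped).  Ratios and MDIN are NaN when their
    denominator is zero.
    """

    md_lp: float
    md_rp: float
    mdi: float
    mdin: float
    mdrlr: float
    mdrrl: float
    n_used: int

    def get(self, metric: MDMetric | str) -> float:
        return float(getattr(self, MDMetric(metric).value))


def _window_slice(curve: SpectralCurve, pivots: PivotPair) -> np.ndarray:
    """Boolean mask of samples whose abscissa lies in [lp, rp]."""
    x = curve.abscissa
    inside = (x >= pivots.lp) & (x <= pivots.rp)
    if not inside.any():
        raise ValueError(
            f"empty pivot window [{pivots.lp}, {pivots.rp}]: no sample of the "
            f"curve's abscissa (range {x[0]}..{x[-1]}) falls inside it"
        )
    return inside


def _windowed(curve: SpectralCurve, pivots: PivotPair, skip_nan: bool):
    inside = _window_slice(curve, pivots)
    rho = curve.reflectance[inside]
    x = curve.abscissa[inside]
    bad = np.isnan(rho)
    if bad.any():
        if not skip_nan:
            raise ValueError(
                f"{int(bad.sum())} NaN reflectance sample(s) inside the pivot "
                "window; pass skip_nan=True to exclude them"
            )
        rho, x = rho[~bad], x[~bad]
        if rho.size == 0:
            raise ValueError("pivot window contains only NaN samples")
    return rho, x


def moment_distance_lp(
    curve: SpectralCurve, pivots: PivotPair, skip_nan: bool = False
) -> float:
    """Moment distance from the left pivot.

    Sum of hypotenuses from ``(lp, 0)`` to each in-window sample
    ``(x_i, rho_i)``: one leg is the reflectance, the other the abscissa
    offset ``x_i - lp``.
    """
    rho, x = _windowed(curve, pivots, skip_nan)
    return float(np.sqrt(rho**2 + (x - pivots.lp) ** 2).sum())


def moment_distance_rp(
    curve: SpectralCurve, pivots: PivotPair, skip_nan: bool = False
) -> float:
    """Moment distance from the right pivot (legs ``rp - x_i``)."""
    rho, x = _windowed(curve, pivots, skip_nan)
    return float(np.sqrt(rho**2 + (pivots.rp - x) ** 2).sum())


def md_metrics(
    curve: SpectralCurve, pivots: PivotPair | None = None, skip_nan: bool = False
) -> MDResult:
    """All moment-distance quantities for one curve.

    With ``pivots`` omitted, the window spans the full curve (first to last
    sample), which is the default use: the whole spectrum contributes.

    A zero MD_LP or MD_RP (possible only for an all-zero curve with
    ``lp == rp``) makes the ratios — and MDIN when both are zero —
    undefined; they are reported as NaN with a warning, never substituted.
    """
    if pivots is None:
        pivots = PivotPair(float(curve.abscissa[0]), float(curve.abscissa[-1]))
    rho, x = _windowed(curve, pivots, skip_nan)
    md_lp = float(np.sqrt(rho**2 + (x - pivots.lp) ** 2).sum())
    md_rp = float(np.sqrt(rho**2 + (pivots.rp - x) ** 2).sum())
    mdi = md_rp - md_lp
    total = md_rp + md_lp
    if md_lp == 0.0 or md_rp == 0.0:
        warnings.warn(
            "zero moment distance: MD ratios (and MDIN if both are zero) are "
            "undefined and reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    mdin = mdi / total if total > 0 else float("nan")
    mdrlr = md_lp / md_rp if md_rp > 0 else float("nan")
    mdrrl = md_rp / md_lp if md_lp > 0 else float("nan")
    return MDResult(md_lp, md_rp, mdi, mdin, mdrlr, mdrrl, int(rho.size))


def md_cube(
    cube: HyperCube,
    pivots: PivotPair | None = None,
    metric: MDMetric | str = MDMetric.MDI,
    units: str = "index",
    skip_nan: bool = False,
    reflectance_scale: float = 1.0,
) -> np.ndarray:
    """Per-pixel moment-distance metric over a whole cube.

    Masked (bad) bands are excluded before the abscissa is formed, so the
    retained bands carry contiguous index positions.  ``pivots`` default to
    the first and last retained band (full-spectrum window).

    ``reflectance_scale`` multiplies the reflectance before the hypotenuses
    are formed.  The MD equations mix reflectance with abscissa distance,
    so their sensitivity to curve shape depends on the two being
    commensurate: with unit-range reflectance against a band-index
    abscissa of hundreds, the abscissa legs swamp the reflectance legs and
    the metrics barely see the curve.  Hyperspectral products that store
    reflectance as 1e4-scaled digital numbers sit naturally in the
    shape-sensitive regime; for a [0, 1] cube, ``reflectance_scale=1e4``
    reproduces that behaviour.

    Returns a ``(rows, cols)`` float array of the chosen metric.
    """
    metric = MDMetric(metric)
    x = cube.abscissa(units)
    if pivots is None:
        pivots = PivotPair(float(x[0]), float(x[-1]))
    if pivots.lp < x[0] or pivots.rp > x[-1]:
        raise ValueError(
            f"pivots [{pivots.lp}, {pivots.rp}] outside the retained abscissa "
            f"range [{x[0]}, {x[-1]}]"
        )
    inside = (x >= pivots.lp) & (x <= pivots.rp)
    if not inside.any():
        raise ValueError(
            f"empty pivot window [{pivots.lp}, {pivots.rp}] on abscissa range "
            f"[{x[0]}, {x[-1]}]"
        )
    rho = cube.retained[inside] * reflectance_scale  # (m, rows, cols)
    xs = x[inside]
    nan_mask = np.isnan(rho)
    if nan_mask.any() and not skip_nan:
        raise ValueError(
            "cube contains NaN reflectance inside the pivot window; pass "
            "skip_nan=True to exclude those samples per pixel"
        )
    legs_lp = (xs - pivots.lp)[:, None, None]
    legs_rp = (pivots.rp - xs)[:, None, None]
    h_lp = np.sqrt(rho**2 + legs_lp**2)
    h_rp = np.sqrt(rho**2 + legs_rp**2)
    if nan_mask.any():
        h_lp = np.where(nan_mask, 0.0, h_lp)
        h_rp = np.where(nan_mask, 0.0, h_rp)
    md_lp = h_lp.sum(axis=0)
    md_rp = h_rp.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric is MDMetric.MDI:
            out = md_rp - md_lp
        elif metric is MDMetric.MDIN:
            out = np.where(md_rp + md_lp > 0, (md_rp - md_lp) / (md_rp + md_lp), np.nan)
        elif metric is MDMetric.MDRLR:
            out = np.where(md_rp > 0, md_lp / md_rp, np.nan)
        else:
            out = np.where(md_lp > 0, md_rp / md_lp, np.nan)
    return out


def md_sweep(curve: SpectralCurve, fixed: str = "LP") -> np.ndarray:
    """Cumulative moment-distance sums with one pivot fixed and one moving.

    A diagnostic for locating *where* along the spectrum two curves' shapes
    diverge.  With ``fixed='LP'`` the left pivot sits at the curve's first
    sample and the window's right end advances band by band; element ``k``
    is MD_LP over the first ``k + 1`` samples, so the last element is the
    full-window MD_LP.  With ``fixed='RP'`` the mirror sweep runs from the
    right end leftward and element ``k`` is MD_RP over the last ``k + 1``
    samples.

    Returns a vector of length ``n``.
    """
    if curve.n < 2:
        raise ValueError("sweep needs a curve with at least 2 samples")
    fixed = fixed.upper()
    rho, x = curve.reflectance, curve.abscissa
    if fixed == "LP":
        legs = x - x[0]
        terms = np.sqrt(rho**2 + legs**2)
        return np.cumsum(terms)
    if fixed == "RP":
        legs = x[-1] - x
        terms = np.sqrt(rho**2 + legs**2)
        return np.cumsum(terms[::-1])
    raise ValueError("fixed must be 'LP' or 'RP'")
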