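"""Second-order texture features from co-occurrence matrices of PC score images.

The texture branch of the pipeline reduces the cube to its three leading
principal-component score images (they carry most of the spectral
variance), then computes five Haralick-style statistics — variance (VAR),
entropy (ENT), correlation (COR), contrast (CON) and angular second moment
(ASM) — of the gray-level co-occurrence matrix (GLCM) inside a moving
window around every pixel.  Three PCs x five statistics = 15 texture
layers, named ``VAR(PCA1)`` ... ``ASM(PCA3)``.

The co-occurrence matrix at a pixel is built from all ordered gray-level
pairs at the configured offset whose *both* endpoints fall inside the
window, pooled over the four standard directions (0, 45, 90, 135 degrees:
each direction's symmetrized matrix is normalized, then the four are
averaged).  Gray levels come from equal-width quantization between the
image's 1st and 99th percentile (values clipped).  Image borders are
reflect-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureStack, HyperCube

__all__ = [
    "PCScores",
    "CooccurrenceConfig",
    "pca_scores",
    "cooccurrence_features",
    "texture_stack",
    "TEXTURE_FEATURES",
]

TEXTURE_FEATURES = ("VAR", "ENT", "COR", "CON", "ASM")

#: (row, col) unit offsets for 0, 45, 90 and 135 degrees.
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class PCScores:
    """Top-k principal-component score images of a cube's band space."""

    scores: np.ndarray  # (k, rows, cols)
    explained_variance: np.ndarray  # fractions, non-increasing

    @property
    def k(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class CooccurrenceConfig:
    """Moving-window GLCM parameters.

    levels
        Gray levels after quantization (default 32).
    distance
        Pixel offset between pair members (default 1).
    window
        Odd side length of the moving window (default 7).
    """

    levels: int = 32
    distance: int = 1
    window: int = 7

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.distance >= self.window:
            raise ValueError("distance must be smaller than the window")


def pca_scores(cube: HyperCube, k: int = 3) -> PCScores:
    """Per-pixel scores on the top-k eigenvectors of the band covariance.

    Bands are mean-centred; pixels containing NaN in any retained band are
    excluded from the covariance estimate (their scores are NaN).  A
    degenerate (constant) cube has no principal axes and raises.
    """
    data = cube.retained  # (m, rows, cols)
    m = data.shape[0]
    if m < k:
        raise ValueError(f"cube has {m} retained bands, need at least k={k}")
    flat = data.reshape(m, -1).T  # (pixels, m)
    valid = ~np.isnan(flat).any(axis=1)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 NaN-free pixels; cannot estimate covariance")
    x = flat[valid]
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (xc.shape[0] - 1)
    total_var = np.trace(cov)
    if total_var <= 0 or not np.isfinite(total_var):
        raise ValueError("degenerate band covariance (constant cube?)")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores_flat = np.full((flat.shape[0], k), np.nan)
    scores_flat[valid] = (flat[valid] - mean) @ evecs
    scores = scores_flat.T.reshape(k, cube.rows, cube.cols)
    return PCScores(scores, np.clip(evals / total_var, 0.0, 1.0))


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization between the 1st and 99th percentile.

    Values outside the percentile span are clipped into the extreme bins.
    A constant image maps entirely to level 0.
    """
    lo, hi = np.nanpercentile(image, [1.0, 99.0])
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _direction_counts(
    qpad: np.ndarray, rows: int, cols: int, w: int, dy: int, dx: int, levels: int
) -> np.ndarray:
    """Per-pixel pair counts for one direction, shape (rows*cols, levels^2).

    ``qpad`` is the quantized image reflect-padded by w//2.  For the window
    centred at each pixel, every ordered pair (p, p + (dy, dx)) with both
    endpoints inside the window is counted.
    """
    counts = np.zeros((rows * cols, levels * levels), dtype=np.float64)
    pix = np.arange(rows * cols)
    a_lo, a_hi = max(0, -dy), w - max(0, dy)  # start-row range within window
    b_lo, b_hi = max(0, -dx), w - max(0, dx)
    for a in range(a_lo, a_hi):
        for b in range(b_lo, b_hi):
            i_codes = qpad[a : a + rows, b : b + cols].ravel()
            j_codes = qpad[a + dy : a + dy + rows, b + dx : b + dx + cols].ravel()
            np.add.at(counts, (pix, i_codes * levels + j_codes), 1.0)
    return counts


def _glcm_stack(image: np.ndarray, cfg: CooccurrenceConfig) -> np.ndarray:
    """Direction-averaged symmetrized normalized GLCM per pixel.

    Returns ``(rows*cols, levels, levels)``.
    """
    rows, cols = image.shape
    w, L, d = cfg.window, cfg.levels, cfg.distance
    if w > rows or w > cols:
        raise ValueError(f"window {w} larger than image {rows}x{cols}")
    if not np.isfinite(image).all():
        raise ValueError("texture input image contains non-finite values")
    q = quantize(image, L)
    pad = w // 2
    qpad = np.pad(q, pad, mode="reflect")
    out = np.zeros((rows * cols, L, L), dtype=np.float64)
    for dy, dx in _DIRECTIONS:
        c = _direction_counts(qpad, rows, cols, w, dy * d, dx * d, L)
        c = c.reshape(-1, L, L)
        c = c + c.transpose(0, 2, 1)  # symmetrize
        totals = c.sum(axis=(1, 2), keepdims=True)
        out += c / totals
    out /= len(_DIRECTIONS)
    return out


def cooccurrence_features(
    image: np.ndarray, cfg: CooccurrenceConfig | None = None
) -> dict[str, np.ndarray]:
    """The five GLCM statistics of every pixel's window.

    Given the normalized symmetric matrix P (levels x levels) per pixel:

        CON = sum (i - j)^2 P_ij
        ASM = sum P_ij^2
        ENT = -sum P_ij ln P_ij            (0 ln 0 = 0)
        VAR = sum (i - mu)^2 P_ij          (mu = matrix mean of i)
        COR = sum (i - mu_i)(j - mu_j) P_ij / (sigma_i sigma_j)

    COR is NaN where a window is constant (zero marginal deviation).
    Returns a dict of five ``(rows, cols)`` rasters.
    """
    cfg = cfg or CooccurrenceConfig()
    image = np.asarray(image, dtype=float)
    rows, cols = image.shape
    P = _glcm_stack(image, cfg)
    L = cfg.levels
    lev = np.arange(L, dtype=float)
    diff2 = (lev[:, None] - lev[None, :]) ** 2

    con = np.einsum("nij,ij->n", P, diff2)
    asm = np.einsum("nij,nij->n", P, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(P), 0.0)
    ent = -np.einsum("nij,nij->n", P, logp)
    p_i = P.sum(axis=2)  # marginal of i (symmetric => same as j)
    mu = p_i @ lev
    var = p_i @ (lev**2) - mu**2
    var = np.maximum(var, 0.0)  # clip fp negatives
    cross = np.einsum("nij,i,j->n", P, lev, lev)
    sigma2 = var
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.where(sigma2 > 0, (cross - mu**2) / sigma2, np.nan)

    shape = (rows, cols)
    return {
        "VAR": var.reshape(shape),
        "ENT": ent.reshape(shape),
        "COR": cor.reshape(shape),
        "CON": con.reshape(shape),
        "ASM": asm.reshape(shape),
    }


def texture_stack(
    cube: HyperCube, cfg: CooccurrenceConfig | None = None, k: int = 3
) -> FeatureStack:
    """The 15 texture layers: five GLCM statistics per top-k PC score image.

    Layer names follow the ``FEAT(PCAk)`` convention, e.g. ``ENT(PCA1)``,
    ``ASM(PCA2)``.
    """
    cfg = cfg or CooccurrenceConfig()
    pcs = pca_scores(cube, k=k)
    stack = FeatureStack(cube.rows, cube.cols)
    for j in range(pcs.k):
        feats = cooccurrence_features(pcs.scores[j], cfg)
        for feat in TEXTURE_FEATURES:
            stack.add(
                f"{feat}(PCA{j + 1})",
                feats[feat],
                operation="glcm_texture",
                component=j + 1,
                levels=cfg.levels,
                distance=cfg.distance,
                window=cfg.window,
            )
    return stack
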