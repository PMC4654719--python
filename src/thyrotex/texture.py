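"""MaZda-style texture feature catalogue over a masked 2D region.

Seven feature families are computed from a raster (typically an ADC map)
restricted to a binary region of interest (ROI):

* gray-level co-occurrence matrix (GLCM) features at 20 pixel offsets
  (4 directions x distances 1..5), 11 Haralick-type statistics each;
* gray-level run-length matrix (RLM) features in 4 directions, 5 each;
* first-order histogram statistics (9);
* absolute-gradient statistics (5);
* causal autoregressive model parameters (5);
* Haar wavelet subband energies at scales 1..3 (12);
* geometric moments of the mask itself (7).

Feature names follow the MaZda convention, e.g. ``S(0,3)SumAverg`` for
the sum-average of the co-occurrence matrix at column offset 0, row
offset 3, or ``WavEnHH_s-3`` for the diagonal-detail energy at scale 3.
In offset tokens ``S(dx,dy)``, dx is the column (x, rightward) offset and
dy the row (y, downward-positive) offset.

Gray levels are quantized to G = 2^bits levels (default 64) after one of
three intensity normalizations; all entropies use the natural logarithm
with the convention 0*log 0 = 0.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats as sps

from .adc import ROIMask

#: the 11 co-occurrence statistics, in registry order
GLCM_FEATURE_NAMES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)

RLM_FEATURE_NAMES = ("ShrtREmp", "LngREmph", "GLevNonUni", "RLNonUni", "Fraction")

#: MaZda-style direction prefixes for run-length features, with the
#: (row, col) scan step for each direction
RLM_DIRECTIONS = OrderedDict([
    ("Horzl", (0, 1)),    # 0 deg
    ("Vertl", (1, 0)),    # 90 deg
    ("45dgr", (-1, 1)),   # 45 deg
    ("135dr", (1, 1)),    # 135 deg
])

#: GLCM offsets (dx, dy): 0, 90, 45(dx=dy, down-right named (d,d)),
#: 135 (d,-d) at distances 1..5
GLCM_OFFSETS = tuple(
    (dx, dy)
    for d in range(1, 6)
    for (dx, dy) in ((d, 0), (0, d), (d, d), (d, -d))
)

WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")


@dataclass
class QuantizedROI:
    """Integer gray levels 1..G inside a mask; 0 outside."""

    levels: np.ndarray
    G: int
    mask: ROIMask
    normalization: str


@dataclass
class GLCMatrix:
    """Symmetric, count-normalized co-occurrence matrix p(i, j).

    ``degenerate`` marks the case where no in-mask pixel pair exists at
    the offset; the matrix is then all zero.
    """

    p: np.ndarray
    offset: tuple[int, int]
    degenerate: bool = False


@dataclass
class TextureConfig:
    """Extraction settings shared across a study.

    ``bits``/``normalization`` control gray-level quantization;
    ``distances`` the GLCM offset lengths; ``scales`` the wavelet
    depths; the ``include_*`` switches turn whole families off.
    ``geometry`` mask descriptors encode nodule position and size and can
    leak acquisition layout into a model, hence their own switch.
    """

    bits: int = 6
    normalization: str = "mu3sigma"
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    scales: tuple[int, ...] = (1, 2, 3)
    include_glcm: bool = True
    include_rlm: bool = True
    include_histogram: bool = True
    include_gradient: bool = True
    include_ar: bool = True
    include_wavelet: bool = True
    include_geometry: bool = True

    def glcm_offsets(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (dx, dy)
            for d in self.distances
            for (dx, dy) in ((d, 0), (0, d), (d, d), (d, -d))
        )


def _offset_token(dx: int, dy: int) -> str:
    return f"S({dx},{dy})"


def quantize_roi(raster: np.ndarray, roi: ROIMask, bits: int = 6,
                 normalization: str = "mu3sigma") -> QuantizedROI:
    """Quantize in-ROI intensities to 1..2^bits gray levels.

    Normalizations: ``minmax`` maps the in-ROI [min, max] onto the level
    range; ``mu3sigma`` maps [mu - 3 sigma, mu + 3 sigma] with clipping;
    ``perc1_99`` maps [P1, P99] with clipping.  A constant ROI maps to
    level 1 everywhere.
    """
    raster = np.asarray(raster, dtype=float)
    mask = roi.mask
    if raster.shape != mask.shape:
        raise ValueError("raster and ROI shapes differ")
    if not mask.any():
        raise ValueError("empty ROI")
    G = 2 ** bits
    vals = raster[mask]
    if normalization == "minmax":
        lo, hi = vals.min(), vals.max()
    elif normalization == "mu3sigma":
        mu, sd = vals.mean(), vals.std()
        lo, hi = mu - 3 * sd, mu + 3 * sd
    elif normalization == "perc1_99":
        lo, hi = np.percentile(vals, [1, 99])
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    levels = np.zeros(raster.shape, dtype=np.int32)
    if hi <= lo:
        levels[mask] = 1
    else:
        q = np.floor((vals - lo) / (hi - lo) * G).astype(np.int32) + 1
        levels[mask] = np.clip(q, 1, G)
    return QuantizedROI(levels=levels, G=G, mask=roi, normalization=normalization)


def glcm(q: QuantizedROI, offset: tuple[int, int]) -> GLCMatrix:
    """Symmetric co-occurrence matrix at pixel displacement (dx, dy).

    All in-mask pixel pairs (p, p + offset) with both endpoints in the
    mask are accumulated in both orders, then normalized to sum 1.
    """
    dx, dy = offset
    if dx == 0 and dy == 0:
        raise ValueError("offset must be nonzero")
    G = q.G
    lev = q.levels
    m = q.mask.mask
    nr, nc = lev.shape
    # source window such that both (r, c) and (r+dy, c+dx) are in bounds
    r0, r1 = max(0, -dy), min(nr, nr - dy)
    c0, c1 = max(0, -dx), min(nc, nc - dx)
    counts = np.zeros((G, G), dtype=float)
    if r1 > r0 and c1 > c0:
        a = lev[r0:r1, c0:c1]
        b = lev[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
        ok = m[r0:r1, c0:c1] & m[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
        ai, bi = a[ok] - 1, b[ok] - 1
        np.add.at(counts, (ai, bi), 1.0)
        np.add.at(counts, (bi, ai), 1.0)
    total = counts.sum()
    if total == 0:
        return GLCMatrix(p=counts, offset=offset, degenerate=True)
    return GLCMatrix(p=counts / total, offset=offset)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with 0 * ln 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_features(m: GLCMatrix) -> "OrderedDict[str, float]":
    """The 11 co-occurrence statistics of one normalized matrix.

    Sum and difference marginals p_{x+y}(k), k = 2..2G, and
    p_{x-y}(k), k = 0..G-1, follow the standard Haralick construction.
    A degenerate (all-zero) matrix yields the point-mass limits
    (entropies 0, contrast 0, correlation 0).
    """
    p = m.p
    G = p.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    mu_x = float(np.sum(i * px))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    # symmetric matrix: x and y marginals coincide
    sd_x = np.sqrt(var_x)

    # sum marginal over k = i + j in 2..2G
    ksum = np.arange(2, 2 * G + 1, dtype=float)
    psum = np.zeros(2 * G - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    # difference marginal over k = |i - j| in 0..G-1
    kdif = np.arange(0, G, dtype=float)
    pdif = np.zeros(G)
    np.add.at(pdif, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    sum_averg = float(np.sum(ksum * psum))
    dif_mean = float(np.sum(kdif * pdif))

    if sd_x > 0:
        correlat = float((np.sum(ii * jj * p) - mu_x * mu_x) / (sd_x * sd_x))
    else:
        correlat = 0.0

    return OrderedDict([
        ("AngScMom", float(np.sum(p * p))),
        ("Contrast", float(np.sum((ii - jj) ** 2 * p))),
        ("Correlat", correlat),
        ("SumOfSqs", var_x),
        ("InvDfMom", float(np.sum(p / (1.0 + (ii - jj) ** 2)))),
        ("SumAverg", sum_averg),
        ("SumVarnc", float(np.sum((ksum - sum_averg) ** 2 * psum))),
        ("SumEntrp", float(-np.sum(_xlogx(psum)))),
        ("Entropy", float(-np.sum(_xlogx(p)))),
        ("DifVarnc", float(np.sum((kdif - dif_mean) ** 2 * pdif))),
        ("DifEntrp", float(-np.sum(_xlogx(pdif)))),
    ])


def _runs_along(levels: np.ndarray, mask: np.ndarray,
                step: tuple[int, int]):
    """Yield (gray_level, run_length) for maximal in-mask runs along lines
    with direction ``step`` (row, col)."""
    nr, nc = levels.shape
    dr, dc = step
    # starting points: pixels with no in-bounds predecessor along -step
    starts = []
    for r in range(nr):
        for c in range(nc):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < nr and 0 <= pc < nc):
                starts.append((r, c))
    for r, c in starts:
        cur_level, cur_len = None, 0
        while 0 <= r < nr and 0 <= c < nc:
            if mask[r, c]:
                g = levels[r, c]
                if g == cur_level:
                    cur_len += 1
                else:
                    if cur_len:
                        yield cur_level, cur_len
                    cur_level, cur_len = g, 1
            else:
                if cur_len:
                    yield cur_level, cur_len
                cur_level, cur_len = None, 0
            r += dr
            c += dc
        if cur_len:
            yield cur_level, cur_len


def rlm_features(q: QuantizedROI, direction: str) -> "OrderedDict[str, float]":
    """Run-length statistics for one scan direction.

    ``direction`` is one of ``Horzl`` (0 deg), ``Vertl`` (90 deg),
    ``45dgr``, ``135dr``.  Runs are maximal same-level pixel sequences
    inside the mask along the direction's scan lines.
    """
    if direction not in RLM_DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    mask = q.mask.mask
    if not mask.any():
        raise ValueError("empty ROI")
    step = RLM_DIRECTIONS[direction]
    # scan only the ROI bounding box; runs cannot cross the mask boundary
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    levels = q.levels[r0:r1, c0:c1]
    mask = mask[r0:r1, c0:c1]
    rlm: dict[tuple[int, int], float] = {}
    for g, length in _runs_along(levels, mask, step):
        rlm[(g, length)] = rlm.get((g, length), 0.0) + 1.0
    n_runs = sum(rlm.values())
    n_px = float(mask.sum())
    if n_runs == 0:
        return OrderedDict((n, 0.0) for n in RLM_FEATURE_NAMES)
    lengths = np.array([l for (_, l) in rlm], dtype=float)
    counts = np.array(list(rlm.values()))
    by_level: dict[int, float] = {}
    by_length: dict[int, float] = {}
    for (g, l), c in rlm.items():
        by_level[g] = by_level.get(g, 0.0) + c
        by_length[l] = by_length.get(l, 0.0) + c
    return OrderedDict([
        ("ShrtREmp", float(np.sum(counts / lengths**2) / n_runs)),
        ("LngREmph", float(np.sum(counts * lengths**2) / n_runs)),
        ("GLevNonUni", float(sum(v * v for v in by_level.values()) / n_runs)),
        ("RLNonUni", float(sum(v * v for v in by_length.values()) / n_runs)),
        ("Fraction", float(n_runs / n_px)),
    ])


def histogram_features(raster: np.ndarray, roi: ROIMask) -> "OrderedDict[str, float]":
    """First-order statistics of in-ROI intensities.

    Variance is the population variance; skewness and excess kurtosis of
    a constant region are defined as 0.  Percentiles use linear
    interpolation between order statistics.
    """
    vals = np.asarray(raster, dtype=float)[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    var = float(vals.var())
    if var > 0:
        skew = float(sps.skew(vals))
        kurt = float(sps.kurtosis(vals))
    else:
        skew = kurt = 0.0
    p01, p10, p50, p90, p99 = np.percentile(vals, [1, 10, 50, 90, 99])
    return OrderedDict([
        ("Mean", float(vals.mean())),
        ("Variance", var),
        ("Skewness", skew),
        ("Kurtosis", kurt),
        ("Perc.01%", float(p01)),
        ("Perc.10%", float(p10)),
        ("Perc.50%", float(p50)),
        ("Perc.90%", float(p90)),
        ("Perc.99%", float(p99)),
    ])


def gradient_features(raster: np.ndarray, roi: ROIMask) -> "OrderedDict[str, float]":
    """Absolute-gradient statistics over interior ROI pixels.

    The gradient magnitude is computed by central differences at in-ROI
    pixels whose four edge-neighbours are also in-ROI.  Returns NaN for
    every statistic if the ROI has no such interior pixel.
    """
    x = np.asarray(raster, dtype=float)
    m = roi.mask
    interior = m.copy()
    interior[[0, -1], :] = False
    interior[:, [0, -1]] = False
    interior[1:-1, 1:-1] &= m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    if not interior.any():
        return OrderedDict(
            (n, float("nan"))
            for n in ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
        )
    gy = np.zeros_like(x)
    gx = np.zeros_like(x)
    gy[1:-1, :] = (x[2:, :] - x[:-2, :]) / 2.0
    gx[:, 1:-1] = (x[:, 2:] - x[:, :-2]) / 2.0
    grad = np.hypot(gx, gy)[interior]
    var = float(grad.var())
    # relative guard: a numerically-constant gradient field is degenerate
    if var > 1e-24 * (1.0 + float(grad.mean()) ** 2):
        skew = float(sps.skew(grad))
        kurt = float(sps.kurtosis(grad))
    else:
        skew = kurt = 0.0
    return OrderedDict([
        ("GrMean", float(grad.mean())),
        ("GrVariance", var),
        ("GrSkewness", skew),
        ("GrKurtosis", kurt),
        ("GrNonZeros", float(np.mean(grad > 0))),
    ])


def ar_features(raster: np.ndarray, roi: ROIMask) -> "OrderedDict[str, float]":
    """Causal autoregressive model parameters Teta1..Teta4 and Sigma.

    Fits x(i,j) = t1*x(i,j-1) + t2*x(i-1,j-1) + t3*x(i-1,j) +
    t4*x(i-1,j+1) + e by least squares over in-ROI pixels whose four
    causal neighbours are in-ROI, on ROI-mean-centred intensities.
    Sigma is the residual standard deviation.  Returns NaN everywhere if
    fewer than 5 usable pixels exist.
    """
    x = np.asarray(raster, dtype=float)
    m = roi.mask
    nr, nc = x.shape
    xc = np.where(m, x - x[m].mean(), 0.0)
    usable = np.zeros_like(m)
    usable[1:, 1:-1] = (
        m[1:, 1:-1]
        & m[1:, :-2]        # (i, j-1)
        & m[:-1, :-2]       # (i-1, j-1)
        & m[:-1, 1:-1]      # (i-1, j)
        & m[:-1, 2:]        # (i-1, j+1)
    )
    names = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")
    rows, cols = np.nonzero(usable)
    if rows.size < 5:
        return OrderedDict((n, float("nan")) for n in names)
    y = xc[rows, cols]
    A = np.column_stack([
        xc[rows, cols - 1],
        xc[rows - 1, cols - 1],
        xc[rows - 1, cols],
        xc[rows - 1, cols + 1],
    ])
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ theta
    sigma = float(np.sqrt(np.mean(resid**2)))
    out = OrderedDict(zip(names[:4], (float(t) for t in theta)))
    out["Sigma"] = sigma
    return out


def wavelet_features(raster: np.ndarray, roi: ROIMask,
                     scales: tuple[int, ...] = (1, 2, 3)) -> "OrderedDict[str, float]":
    """Haar subband energies WavEn{LL,LH,HL,HH}_s-{s} over the ROI.

    The ROI bounding box is padded by edge replication to a multiple of
    2^max(scales), then decomposed with the non-overlapping Haar block
    transform.  Each scale-s coefficient covers a 2^s x 2^s pixel block;
    the energy is the mean squared coefficient over blocks overlapping
    the mask.  Scales whose coefficient grid would be empty, or whose
    bounding box is smaller than 2^s in either dimension, yield NaN.
    """
    x = np.asarray(raster, dtype=float)
    m = roi.mask
    if not m.any():
        raise ValueError("empty ROI")
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    box = x[r0:r1, c0:c1]
    boxmask = m[r0:r1, c0:c1]
    smax = max(scales)
    block = 2 ** smax
    pad_r = (-box.shape[0]) % block
    pad_c = (-box.shape[1]) % block
    box = np.pad(box, ((0, pad_r), (0, pad_c)), mode="edge")
    boxmask = np.pad(boxmask, ((0, pad_r), (0, pad_c)), mode="edge")

    out: "OrderedDict[str, float]" = OrderedDict()
    approx = box
    h0, w0 = m[r0:r1, c0:c1].shape
    for s in sorted(scales):
        undefined = h0 < 2 ** s or w0 < 2 ** s
        cA, (cH, cV, cD) = pywt.dwt2(approx, "haar", mode="periodization")
        blk = 2 ** s
        # a coefficient overlaps the mask if any pixel of its block is in-mask
        nbr = boxmask.shape[0] // blk
        nbc = boxmask.shape[1] // blk
        overlap = boxmask[:nbr * blk, :nbc * blk].reshape(
            nbr, blk, nbc, blk).any(axis=(1, 3))
        for band, coef in zip(WAVELET_SUBBANDS, (cA, cH, cV, cD)):
            name = f"WavEn{band}_s-{s}"
            sel = coef[:nbr, :nbc][overlap]
            if undefined or sel.size == 0:
                out[name] = float("nan")
            else:
                out[name] = float(np.mean(sel**2))
        approx = cA
    return out


def geometry_features(roi: ROIMask) -> "OrderedDict[str, float]":
    """Moment-based descriptors of the binary mask.

    GeoX/GeoY are the mask centroid column/row in the image frame (pixels);
    GeoXo/GeoYo the centroid offsets from the bounding-box origin, and
    GeoXYo their product.  GeoS2 is the area-normalized total second
    central moment (mu20 + mu02)/A and GeoM2xy the area-normalized mixed
    second central moment mu11/A.
    """
    m = roi.mask
    if not m.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(m)
    cy, cx = rows.mean(), cols.mean()
    r0, c0 = rows.min(), cols.min()
    dy = rows - cy
    dx = cols - cx
    area = rows.size
    return OrderedDict([
        ("GeoY", float(cy)),
        ("GeoX", float(cx)),
        ("GeoYo", float(cy - r0)),
        ("GeoXo", float(cx - c0)),
        ("GeoXYo", float((cy - r0) * (cx - c0))),
        ("GeoS2", float((np.sum(dy**2) + np.sum(dx**2)) / area)),
        ("GeoM2xy", float(np.sum(dx * dy) / area)),
    ])


def feature_names(config: TextureConfig) -> list[str]:
    """The ordered registry of feature names implied by a config."""
    names: list[str] = []
    if config.include_glcm:
        for dx, dy in config.glcm_offsets():
            tok = _offset_token(dx, dy)
            names.extend(tok + f for f in GLCM_FEATURE_NAMES)
    if config.include_rlm:
        for direction in RLM_DIRECTIONS:
            names.extend(f"{direction}_{f}" for f in RLM_FEATURE_NAMES)
    if config.include_histogram:
        names.extend(["Mean", "Variance", "Skewness", "Kurtosis",
                      "Perc.01%", "Perc.10%", "Perc.50%", "Perc.90%", "Perc.99%"])
    if config.include_gradient:
        names.extend(["GrMean", "GrVariance", "GrSkewness", "GrKurtosis",
                      "GrNonZeros"])
    if config.include_ar:
        names.extend(["Teta1", "Teta2", "Teta3", "Teta4", "Sigma"])
    if config.include_wavelet:
        for s in sorted(config.scales):
            names.extend(f"WavEn{b}_s-{s}" for b in WAVELET_SUBBANDS)
    if config.include_geometry:
        names.extend(["GeoY", "GeoX", "GeoYo", "GeoXo", "GeoXYo",
                      "GeoS2", "GeoM2xy"])
    return names


_GLCM_FORMULAS = {
    "AngScMom": "sum_ij p(i,j)^2",
    "Contrast": "sum_ij (i-j)^2 p(i,j)",
    "Correlat": "(sum_ij i j p(i,j) - mu_x mu_y) / (sigma_x sigma_y)",
    "SumOfSqs": "sum_ij (i - mu_x)^2 p(i,j)",
    "InvDfMom": "sum_ij p(i,j) / (1 + (i-j)^2)",
    "SumAverg": "sum_k k p_{x+y}(k), k = 2..2G",
    "SumVarnc": "sum_k (k - SumAverg)^2 p_{x+y}(k)",
    "SumEntrp": "-sum_k p_{x+y}(k) ln p_{x+y}(k)",
    "Entropy": "-sum_ij p(i,j) ln p(i,j)",
    "DifVarnc": "sum_k (k - mean of p_{x-y})^2 p_{x-y}(k), k = 0..G-1",
    "DifEntrp": "-sum_k p_{x-y}(k) ln p_{x-y}(k)",
}

_RLM_FORMULAS = {
    "ShrtREmp": "(1/C) sum_{g,l} r(g,l) / l^2",
    "LngREmph": "(1/C) sum_{g,l} r(g,l) l^2",
    "GLevNonUni": "(1/C) sum_g (sum_l r(g,l))^2",
    "RLNonUni": "(1/C) sum_l (sum_g r(g,l))^2",
    "Fraction": "C / N (runs per ROI pixel)",
}

_SCALAR_FORMULAS = {
    "Mean": "mean of in-ROI intensities x",
    "Variance": "population variance of x",
    "Skewness": "mu3(x) / sigma(x)^3",
    "Kurtosis": "mu4(x) / sigma(x)^4 - 3",
    "GrMean": "mean of g = sqrt(Gx^2 + Gy^2), central differences at "
              "interior ROI pixels",
    "GrVariance": "population variance of g",
    "GrSkewness": "mu3(g) / sigma(g)^3",
    "GrKurtosis": "mu4(g) / sigma(g)^4 - 3",
    "GrNonZeros": "fraction of interior ROI pixels with g > 0",
    "Teta1": "LS coefficient of neighbor (i, j-1) in the causal "
             "autoregressive fit on mean-centred intensities",
    "Teta2": "LS coefficient of neighbor (i-1, j-1)",
    "Teta3": "LS coefficient of neighbor (i-1, j)",
    "Teta4": "LS coefficient of neighbor (i-1, j+1)",
    "Sigma": "RMS residual of the autoregressive fit",
    "GeoY": "mask centroid row (pixels, image frame)",
    "GeoX": "mask centroid column (pixels, image frame)",
    "GeoYo": "centroid row offset from bounding-box top",
    "GeoXo": "centroid column offset from bounding-box left",
    "GeoXYo": "GeoYo * GeoXo",
    "GeoS2": "(mu20 + mu02) / A, area-normalized second central moments",
    "GeoM2xy": "mu11 / A, area-normalized mixed second central moment",
}


def feature_registry(config: TextureConfig | None = None
                     ) -> "OrderedDict[str, str]":
    """Ordered name -> formula map for every feature a config produces.

    Notation: p(i,j) is the symmetric normalized co-occurrence matrix for
    the offset named in the prefix S(dx,dy) (dx columns rightward, dy rows
    downward); p_{x+y} and p_{x-y} are its diagonal marginals; r(g,l) the
    run-length matrix (level g, length l) with C total runs and N ROI
    pixels; percentiles, moments and gradient statistics act on raw
    in-ROI intensities.
    """
    if config is None:
        config = TextureConfig()
    registry: "OrderedDict[str, str]" = OrderedDict()
    for name in feature_names(config):
        if name.startswith("S("):
            tok, stat = name.rsplit(")", 1)
            registry[name] = (f"{_GLCM_FORMULAS[stat]}  "
                              f"[co-occurrence offset {tok})]")
        elif "_" in name and name.split("_", 1)[0] in RLM_DIRECTIONS:
            direction, stat = name.split("_", 1)
            dr, dc = RLM_DIRECTIONS[direction]
            registry[name] = (f"{_RLM_FORMULAS[stat]}  "
                              f"[runs along step (dr={dr}, dc={dc})]")
        elif name.startswith("Perc."):
            q = name[5:].rstrip("%")
            registry[name] = f"{q}th percentile of in-ROI intensities"
        elif name.startswith("WavEn"):
            band = name[5:7]
            scale = name.rsplit("-", 1)[1]
            registry[name] = (f"mean squared Haar coefficient, subband "
                              f"{band}, scale {scale}, over ROI-overlapping "
                              f"blocks")
        else:
            registry[name] = _SCALAR_FORMULAS[name]
    return registry


def extract_all(raster: np.ndarray, roi: ROIMask,
                config: TextureConfig | None = None) -> "OrderedDict[str, float]":
    """Concatenate every enabled feature family for one slice ROI.

    The result is an ordered name -> value map matching
    :func:`feature_names`; features undefined for this ROI (e.g. wavelet
    scale exceeding the bounding box) are NaN and should be handled by
    the table-building layer.  Deterministic given inputs and config.
    """
    if config is None:
        config = TextureConfig()
    out: "OrderedDict[str, float]" = OrderedDict()
    q = None
    if config.include_glcm or config.include_rlm:
        q = quantize_roi(raster, roi, config.bits, config.normalization)
    if config.include_glcm:
        for dx, dy in config.glcm_offsets():
            tok = _offset_token(dx, dy)
            for name, val in glcm_features(glcm(q, (dx, dy))).items():
                out[tok + name] = val
    if config.include_rlm:
        for direction in RLM_DIRECTIONS:
            for name, val in rlm_features(q, direction).items():
                out[f"{direction}_{name}"] = val
    if config.include_histogram:
        out.update(histogram_features(raster, roi))
    if config.include_gradient:
        out.update(gradient_features(raster, roi))
    if config.include_ar:
        out.update(ar_features(raster, roi))
    if config.include_wavelet:
        out.update(wavelet_features(raster, roi, config.scales))
    if config.include_geometry:
        out.update(geometry_features(roi))
    return out
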