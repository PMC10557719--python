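"""Pixel-level two-channel colocalization.

Pearson correlation with Costes automatic thresholding and a spatial
block-randomization significance test, plus Otsu-mask overlap fractions.

The Costes procedure fits an orthogonal (total-least-squares) regression of
channel 2 on channel 1 over the ROI, then walks candidate thresholds down
from the channel-1 maximum (with the channel-2 threshold slaved to the
regression line) until the pixels *below* both thresholds are uncorrelated
(r <= 0).  Pixels above threshold in either channel then define the
colocalized population whose Pearson r is reported.  Significance comes
from comparing the observed r with that of images whose blocks (about one
point-spread-function across) have been spatially permuted.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    ArgumentError,
    DegenerateHistogramError,
    DegenerateMaskError,
    UndefinedCorrelationError,
)
from .types import ColocResult, ImagePair, OverlapResult

__all__ = [
    "pearson_r",
    "costes_thresholds",
    "costes_randomization_test",
    "coloc_analysis",
    "otsu_threshold",
    "overlap_fraction",
    "overlap_from_masks",
]

#: Otsu histogram resolution (ImageJ dialect: 256 equal-width bins)
N_OTSU_BINS = 256


def _masked(ch1, ch2, mask):
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ArgumentError("channel shapes differ")
    if mask is None:
        mask = np.ones(ch1.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ch1.shape:
            raise ArgumentError("mask shape does not match channels")
    return ch1[mask], ch2[mask]


def pearson_r(ch1, ch2, mask=None):
    """Pearson product-moment correlation over masked pixels.

    Raises
    ------
    ArgumentError
        Fewer than 2 masked pixels.
    UndefinedCorrelationError
        A channel is constant within the mask.
    """
    x, y = _masked(ch1, ch2, mask)
    if x.size < 2:
        raise ArgumentError(f"need >= 2 masked pixels, got {x.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd * xd))
    sy = np.sqrt(np.sum(yd * yd))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError(
            "a channel is constant within the mask; correlation undefined"
        )
    return float(np.clip(np.sum(xd * yd) / (sx * sy), -1.0, 1.0))


def _orthogonal_regression(x, y):
    """Total-least-squares line y = slope*x + intercept through a point cloud."""
    xm, ym = x.mean(), y.mean()
    sxx = np.mean((x - xm) ** 2)
    syy = np.mean((y - ym) ** 2)
    sxy = np.mean((x - xm) * (y - ym))
    if sxy == 0 and sxx >= syy:
        slope = 0.0
    else:
        # principal axis of the 2x2 covariance matrix
        d = syy - sxx
        slope = (d + np.hypot(d, 2.0 * sxy)) / (2.0 * sxy) if sxy != 0 else np.inf
    intercept = ym - slope * xm if np.isfinite(slope) else np.nan
    return float(slope), float(intercept)


def costes_thresholds(pair: ImagePair):
    """Costes automatic thresholds for an image pair.

    Returns
    -------
    (t1, t2, slope, intercept, degenerate)
        ``t1``/``t2`` are the per-channel thresholds; ``degenerate`` is True
        when the below-threshold population never decorrelates before the
        channel minima (perfectly colocalized limit), in which case the
        minima are returned.

    Notes
    -----
    The scan granularity is the set of unique sorted channel-1 values
    (exact; no binning).  Candidates with fewer than 2 below-threshold
    pixels, or with a constant below-threshold channel, are skipped.
    """
    x, y = _masked(pair.ch1, pair.ch2, pair.mask)
    if x.size < 2:
        raise ArgumentError("ROI must contain >= 2 pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant channel within ROI")

    slope, intercept = _orthogonal_regression(x, y)
    candidates = np.unique(x)[::-1]  # descending from max(ch1)
    for t1 in candidates:
        t2 = slope * t1 + intercept
        below = (x < t1) & (y < t2)
        if below.sum() < 2:
            continue
        xb, yb = x[below], y[below]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        r_below = pearson_r(xb, yb)
        if r_below <= 0.0:
            return float(t1), float(t2), slope, intercept, False
    t1 = float(x.min())
    return t1, float(slope * t1 + intercept), slope, intercept, True


def _block_groups(shape, block):
    """Tile a bounding box into block x block tiles, grouped by tile shape."""
    ny, nx = shape
    groups = {}
    for i0 in range(0, ny, block):
        for j0 in range(0, nx, block):
            i1, j1 = min(i0 + block, ny), min(j0 + block, nx)
            groups.setdefault((i1 - i0, j1 - j0), []).append((i0, j0))
    return groups


def costes_randomization_test(pair: ImagePair, n=100, block=5, seed=0):
    """Costes block-randomization significance test for colocalization.

    The observed Pearson r over the ROI is compared with the r of ``n``
    surrogate images in which non-overlapping ``block`` x ``block`` tiles
    of channel 2 (over the ROI bounding box) are randomly permuted; tiles
    of equal shape (including partial edge tiles) are exchanged among
    themselves.  Returns the one-sided add-one p-value
    ``(1 + #{r_rand >= r_obs}) / (n + 1)``.
    """
    if n < 1:
        raise ArgumentError(f"n must be >= 1, got {n}")
    if block < 1:
        raise ArgumentError("block must be >= 1")
    mask = pair.mask
    if not mask.any():
        raise ArgumentError("empty ROI")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    ch1, ch2, m = pair.ch1[sl], pair.ch2[sl], mask[sl]

    groups = _block_groups(ch1.shape, block)
    n_blocks = sum(len(v) for v in groups.values())
    if n_blocks < 10:
        raise ArgumentError(
            f"ROI too small for randomization: {n_blocks} blocks < 10"
        )

    r_obs = pearson_r(ch1, ch2, m)
    rng = np.random.default_rng(seed)
    shuffled = np.empty_like(ch2)
    count = 0
    for _ in range(n):
        for shape_key, origins in groups.items():
            perm = rng.permutation(len(origins))
            bh, bw = shape_key
            for (i0, j0), p in zip(origins, perm):
                si0, sj0 = origins[p]
                shuffled[i0:i0 + bh, j0:j0 + bw] = ch2[si0:si0 + bh, sj0:sj0 + bw]
        if pearson_r(ch1, shuffled, m) >= r_obs:
            count += 1
    return (1.0 + count) / (n + 1.0)


def coloc_analysis(pair: ImagePair, n_rand=100, block=5, seed=0) -> ColocResult:
    """Full Costes-thresholded Pearson analysis of one image pair.

    Computes the Costes thresholds, the Pearson r over ROI pixels above
    threshold in either channel (``r``; falls back to the whole-ROI r for
    degenerate threshold returns), the whole-ROI r (``r_all``), and the
    block-randomization p-value.
    """
    mask = pair.mask
    if not mask.any():
        raise ArgumentError("empty ROI")
    t1, t2, slope, intercept, degenerate = costes_thresholds(pair)
    r_all = pearson_r(pair.ch1, pair.ch2, mask)
    above = mask & ((pair.ch1 >= t1) | (pair.ch2 >= t2))
    try:
        r_above = pearson_r(pair.ch1, pair.ch2, above)
    except (ArgumentError, UndefinedCorrelationError):
        r_above = r_all
    p = costes_randomization_test(pair, n=n_rand, block=block, seed=seed)
    return ColocResult(
        r=r_above,
        r_all=r_all,
        t1=t1,
        t2=t2,
        slope=slope,
        intercept=intercept,
        p_value=p,
        n_randomizations=n_rand,
        degenerate=degenerate,
    )


def otsu_threshold(img, mask=None):
    """Otsu threshold over a 256-equal-width-bin histogram of masked pixels.

    The returned threshold is the bin edge maximizing between-class
    variance (classes: below vs at-or-above threshold); ties are broken
    toward the lower threshold.

    Raises
    ------
    DegenerateHistogramError
        Constant image within the mask.
    """
    img = np.asarray(img, dtype=float)
    if mask is None:
        vals = img.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ArgumentError("mask shape does not match image")
        vals = img[mask]
    if vals.size < 2:
        raise ArgumentError("need >= 2 masked pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")

    hist, edges = np.histogram(vals, bins=N_OTSU_BINS, range=(lo, hi))
    sums, _ = np.histogram(vals, bins=N_OTSU_BINS, range=(lo, hi), weights=vals)
    n = hist.sum()
    omega = np.cumsum(hist) / n  # class-0 weight for split after bin k
    mu = np.cumsum(sums) / n  # class-0 first moment (exact, from pixel sums)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-np.inf)  # splits k = 0..254
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(edges[k + 1])


def overlap_from_masks(mask1, mask2) -> OverlapResult:
    """Overlap fractions from two boolean masks (AND overlap map)."""
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    if mask1.shape != mask2.shape:
        raise ArgumentError("mask shapes differ")
    a1, a2 = int(mask1.sum()), int(mask2.sum())
    ov = int((mask1 & mask2).sum())
    if a1 == 0 or a2 == 0:
        raise DegenerateMaskError(
            f"empty channel mask (areas ch1={a1}, ch2={a2})",
            area_ch1=a1, area_ch2=a2, area_overlap=ov,
        )
    return OverlapResult(
        frac_ch1=ov / a1, frac_ch2=ov / a2,
        area_ch1=a1, area_ch2=a2, area_overlap=ov,
    )


def overlap_fraction(pair: ImagePair, dialect="and") -> OverlapResult:
    """Otsu-mask overlap fractions for an image pair.

    Each channel is thresholded with Otsu (within the ROI) to a mask.  The
    overlap map is the pixelwise AND of the two masks (``dialect="and"``,
    default); the ``"product"`` dialect instead Otsu-thresholds the
    pixelwise product image ch1*ch2 and intersects that with each channel
    mask.  Each fraction is the overlap area divided by that channel's
    mask area.
    """
    if dialect not in ("and", "product"):
        raise ArgumentError(f"unknown overlap dialect {dialect!r}")
    mask = pair.mask
    t1 = otsu_threshold(pair.ch1, mask)
    t2 = otsu_threshold(pair.ch2, mask)
    m1 = mask & (pair.ch1 >= t1)
    m2 = mask & (pair.ch2 >= t2)
    a1, a2 = int(m1.sum()), int(m2.sum())
    if a1 == 0 or a2 == 0:
        raise DegenerateMaskError(
            f"empty channel mask after Otsu (areas ch1={a1}, ch2={a2})",
            area_ch1=a1, area_ch2=a2,
        )
    if dialect == "and":
        overlap = m1 & m2
    else:
        prod = pair.ch1 * pair.ch2
        try:
            tp = otsu_threshold(prod, mask)
            overlap = mask & (prod >= tp) & m1 & m2
        except DegenerateHistogramError:
            overlap = m1 & m2
    ov = int(overlap.sum())
    return OverlapResult(
        frac_ch1=ov / a1, frac_ch2=ov / a2,
        area_ch1=a1, area_ch2=a2, area_overlap=ov,
    )
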