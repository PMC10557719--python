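"""FRAP trace processing: correction, normalization, fitting, pooling.

The processing chain mirrors standard confocal FRAP practice for a slowly
turning-over matrix protein:

1. ``register_xy`` — optional integer-pixel XY drift correction of the
   raw time series (translation only).
2. ``correct_trace`` — background/autofluorescence subtraction and
   ratiometric acquisition-bleaching correction against a non-bleached
   reference ROI.
3. ``normalize_trace`` — affine normalization
   ``(F_t - F_bleach) / (F_ini - F_bleach)`` where ``F_bleach`` is the
   corrected intensity at the frame immediately after bleaching and
   ``F_ini`` the mean corrected pre-bleach intensity; the bleach frame maps
   exactly to 0 and the pre-bleach mean exactly to 1.
4. ``fit_one_phase`` — least-squares fit of the one-phase association
   ``Y(t) = Y0 + (Plateau - Y0)(1 - e^(-K t))`` to the post-bleach points,
   gated at r² > 0.9.
5. ``immobile_fraction`` — ``1 - (Plateau - Y0) / (1 - Y0)``; because the
   normalization pins the bleach frame to 0, a noiseless fit has Y0 = 0
   and the fitted plateau is the mobile fraction directly.

Note the normalization is invariant under affine maps of the corrected
trace, so the physical bleach depth is not separately identifiable from a
normalized trace: the identifiable parameters are the recovery rate K and
the mobile fraction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .errors import (
    ArgumentError,
    DivisionByBackgroundError,
    FitFailureError,
    NoBleachError,
)
from .types import FrapFit, FrapTrace

__all__ = [
    "register_xy",
    "correct_trace",
    "normalize_trace",
    "process_trace",
    "fit_one_phase",
    "immobile_fraction",
    "pool_curves",
]

logger = logging.getLogger(__name__)

#: goodness-of-fit acceptance gate on r-squared
R2_GATE = 0.9


def register_xy(frames, max_shift=None):
    """Align a raster time series to its first frame by integer translation.

    Each frame is shifted by the integer translation maximizing its
    cross-correlation with the first frame; the stack of aligned frames
    and the per-frame drifts (dy, dx) — each frame's estimated
    displacement relative to the first, i.e. the negative of the applied
    correction — are returned.  ``max_shift`` caps the allowed
    displacement; a shift at the cap triggers a warning (featureless
    frames cannot be registered reliably).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ArgumentError("need >= 2 frames of identical shape (T, Y, X)")
    ny, nx = frames.shape[1:]
    if max_shift is None:
        max_shift = min(ny, nx) // 4
    ref = frames[0]
    aligned = np.empty_like(frames)
    aligned[0] = frames[0]
    shifts = [(0, 0)]
    for i in range(1, frames.shape[0]):
        shift, _, _ = phase_cross_correlation(ref, frames[i], upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        if abs(dy) > max_shift or abs(dx) > max_shift:
            logger.warning(
                "frame %d: shift (%d, %d) exceeds max_shift=%d; clamped "
                "(frames may be featureless)",
                i, dy, dx, max_shift,
            )
            dy = int(np.clip(dy, -max_shift, max_shift))
            dx = int(np.clip(dx, -max_shift, max_shift))
        aligned[i] = ndimage.shift(frames[i], (dy, dx), order=0, mode="nearest")
        shifts.append((-dy, -dx))
    return aligned, shifts


def correct_trace(trace: FrapTrace) -> np.ndarray:
    """Background-subtract and bleach-correct a raw ROI trace.

    ``corrected(t) = (roi(t) - background) / b(t)`` with the bleach factor
    ``b(t) = (ref(t) - background) / mean_prebleach(ref - background)``
    from the non-bleached reference ROI.  Ratiometric correction is exact
    under multiplicative acquisition bleaching.  Values are not clipped;
    negative corrected intensities are retained so normalization stays
    affine.
    """
    ref_bg = trace.ref - trace.background
    if np.any(ref_bg == 0):
        frame = int(np.nonzero(ref_bg == 0)[0][0])
        raise DivisionByBackgroundError(
            f"reference equals background at frame {frame}"
        )
    ref_pre = ref_bg[: trace.n_prebleach].mean()
    if ref_pre == 0:
        raise DivisionByBackgroundError("pre-bleach reference mean equals background")
    b = ref_bg / ref_pre
    return (trace.roi - trace.background) / b


def normalize_trace(corrected, n_prebleach, bleach_index=None):
    """Normalize a corrected trace to (F_t - F_bleach)/(F_ini - F_bleach).

    ``F_ini`` is the mean corrected intensity of the pre-bleach frames and
    ``F_bleach`` the corrected intensity at the frame immediately after
    bleaching.  By construction the bleach frame maps exactly to 0 and the
    pre-bleach mean exactly to 1.
    """
    corrected = np.asarray(corrected, dtype=float)
    if n_prebleach < 1:
        raise ArgumentError("n_prebleach must be >= 1")
    if bleach_index is None:
        bleach_index = n_prebleach
    if bleach_index >= len(corrected):
        raise ArgumentError("bleach_index beyond end of trace")
    f_ini = corrected[:n_prebleach].mean()
    f_bleach = corrected[bleach_index]
    if f_ini == f_bleach:
        raise NoBleachError("F_ini equals F_bleach: no detectable bleach")
    return (corrected - f_bleach) / (f_ini - f_bleach)


def process_trace(trace: FrapTrace):
    """Correct and normalize a raw trace; returns (t_post, normalized_post).

    Convenience wrapper chaining :func:`correct_trace` and
    :func:`normalize_trace` and slicing out the post-bleach portion on
    which the recovery is fitted.
    """
    norm = normalize_trace(correct_trace(trace), trace.n_prebleach, trace.bleach_index)
    return trace.t[trace.bleach_index:], norm[trace.bleach_index:]


def _one_phase(t, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def fit_one_phase(t, y, r2_gate=R2_GATE, trace_id="") -> FrapFit:
    """Fit the one-phase association ``Y0 + (Plateau - Y0)(1 - e^(-K t))``.

    ``t`` and ``y`` are the post-bleach time (s, starting at 0) and
    normalized intensity.  Initialization: Y0 from the first point,
    Plateau from the mean of the last 5 points, K from the time to half
    recovery; K is bounded positive.  ``accepted`` is the r² > 0.9 gate.
    A flat trace returns plateau = y0 with ``k_identifiable=False``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ArgumentError("t and y lengths differ")
    if len(t) < 4:
        raise ArgumentError(f"need >= 4 post-bleach points, got {len(t)}")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0 or np.ptp(y) < 1e-12:
        val = float(y.mean())
        m, im = _fractions(val, val)
        return FrapFit(y0=val, plateau=val, k=np.nan, r2=1.0,
                       mobile_fraction=m, immobile_fraction=im,
                       accepted=True, k_identifiable=False, trace_id=trace_id)

    y0_init = float(y[0])
    plateau_init = float(y[-min(5, len(y)):].mean())
    half = y0_init + 0.5 * (plateau_init - y0_init)
    if plateau_init > y0_init:
        idx = np.nonzero(y >= half)[0]
    else:
        idx = np.nonzero(y <= half)[0]
    t_half = t[idx[0]] if idx.size and t[idx[0]] > 0 else (t[-1] - t[0]) / 4 or 1.0
    k_init = np.log(2.0) / t_half

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _one_phase, t, y,
                p0=[y0_init, plateau_init, k_init],
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise FitFailureError(
            f"one-phase fit did not converge (n={len(t)}, "
            f"init=({y0_init:.3g}, {plateau_init:.3g}, {k_init:.3g})): {exc}"
        ) from exc
    y0, plateau, k = (float(v) for v in popt)
    ss_res = float(np.sum((y - _one_phase(t, *popt)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    m, im = _fractions(y0, plateau)
    accepted = r2 > r2_gate
    if not accepted:
        logger.info("trace %s rejected: r2=%.4f <= %.2f", trace_id or "?", r2, r2_gate)
    return FrapFit(y0=y0, plateau=plateau, k=k, r2=r2,
                   mobile_fraction=m, immobile_fraction=im,
                   accepted=accepted, trace_id=trace_id)


def _fractions(y0, plateau):
    if y0 >= 1.0:
        raise ArgumentError(
            f"immobile fraction undefined: Y0={y0} >= 1 (full pre-bleach retention)"
        )
    mobile = (plateau - y0) / (1.0 - y0)
    return mobile, 1.0 - mobile


def immobile_fraction(fit) -> float:
    """Immobile fraction ``1 - (Plateau - Y0)/(1 - Y0)`` of a fit.

    Accepts a :class:`FrapFit` or a ``(y0, plateau)`` pair.  The mobile
    fraction is its complement, so mobile + immobile = 1 exactly.
    """
    if isinstance(fit, FrapFit):
        y0, plateau = fit.y0, fit.plateau
    else:
        y0, plateau = fit
    _, im = _fractions(y0, plateau)
    return im


def pool_curves(curves, t=None):
    """Pointwise mean and sample SD of normalized curves on a common grid.

    Returns ``(mean, sd, n)`` arrays; ``sd`` is the ddof=1 sample standard
    deviation (0 for a single curve).  All curves must share the time grid.
    """
    curves = [np.asarray(c, dtype=float) for c in curves]
    if not curves:
        raise ArgumentError("need >= 1 curve")
    length = len(curves[0])
    for i, c in enumerate(curves):
        if len(c) != length:
            raise ArgumentError(
                f"curve {i} has {len(c)} points, expected {length} (grid mismatch)"
            )
    if t is not None and len(t) != length:
        raise ArgumentError("time grid length mismatch")
    arr = np.vstack(curves)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(length)
    n = np.full(length, arr.shape[0])
    return mean, sd, n
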