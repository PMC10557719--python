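"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the four kinds of raw data the quantification
pipeline consumes — two-channel BM-like image pairs, FRAP ROI traces,
follicle intensity/depth time series, and annotated division geometries —
with the true parameter of interest programmed in, so every estimator
downstream can be validated against a known answer.

All randomness flows from one explicit integer seed per call
(``numpy.random.default_rng``); there is no global state, and identical
arguments plus seed give bit-identical output.
"""

from __future__ import annotations

import numpy as np

from .errors import ArgumentError
from .types import (
    ColocGroundTruth,
    DivisionGeometry,
    FollicleSeries,
    FrapGroundTruth,
    FrapTrace,
    ImagePair,
)

__all__ = [
    "gen_correlated_pair",
    "gen_frap_trace",
    "gen_follicle_series",
    "gen_division_geometry",
]


def _sheet_mask(shape, rng, width=5.0):
    """Curvilinear band emulating a thin, undulating basement membrane.

    The band's centerline is a low-frequency sinusoid across the image;
    pixels within ``width/2`` (vertical distance) of it are foreground.
    """
    ny, nx = shape
    x = np.arange(nx)
    amp = 0.18 * ny
    period = nx / rng.uniform(1.5, 2.5)
    phase = rng.uniform(0, 2 * np.pi)
    center = ny / 2 + amp * np.sin(2 * np.pi * x / period + phase)
    yy = np.arange(ny)[:, None]
    return np.abs(yy - center[None, :]) <= width / 2.0


def gen_correlated_pair(
    shape=(128, 128),
    rho=0.8,
    structure="flat",
    noise_sigma=20.0,
    seed=0,
    base=500.0,
    amplitude=100.0,
    background=50.0,
):
    """Generate a two-channel image pair with a known pixel correlation.

    Within the foreground mask both channels fluctuate around ``base``; the
    fluctuations are drawn from an exact bivariate normal whose correlation
    is ``rho``.  The construction mixes one shared latent Gaussian field
    with per-channel independent fields, with the mixing weight chosen so
    the population correlation equals ``rho`` exactly; ``noise_sigma``
    (detector noise) contributes to the independent component's variance,
    so the programmed correlation already accounts for it.  ``rho = 1``
    with ``noise_sigma = 0`` therefore makes channel 2 an affine image of
    channel 1.

    Parameters
    ----------
    shape
        Raster dimensions (rows, cols).
    rho
        Target pixel correlation in [-1, 1] inside the foreground.
    structure
        ``"flat"`` — the whole frame is foreground; ``"sheet"`` — a ~5 px
        sinusoidal band emulating a basement membrane, the rest dim
        background.
    noise_sigma
        Detector-noise standard deviation (a.u.), folded into the
        independent fluctuation component.
    seed
        Integer seed; identical calls are bit-reproducible.

    Returns
    -------
    (ImagePair, ColocGroundTruth)
    """
    if not -1.0 <= rho <= 1.0:
        raise ArgumentError(f"rho must lie in [-1, 1], got {rho}")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) <= 0:
        raise ArgumentError(f"shape must be two positive dims, got {shape}")
    if structure not in ("flat", "sheet"):
        raise ArgumentError(f"structure must be 'flat' or 'sheet', got {structure!r}")
    if noise_sigma < 0:
        raise ArgumentError("noise_sigma must be non-negative")

    rng = np.random.default_rng(seed)
    if structure == "flat":
        fg = np.ones(shape, dtype=bool)
    else:
        fg = _sheet_mask(shape, rng)

    sigma_tot = float(np.hypot(amplitude, noise_sigma))
    a = abs(rho)
    shared = rng.standard_normal(shape)
    e1 = rng.standard_normal(shape)
    e2 = rng.standard_normal(shape)
    f1 = np.sqrt(a) * shared + np.sqrt(1.0 - a) * e1
    sign = 1.0 if rho >= 0 else -1.0
    f2 = sign * np.sqrt(a) * shared + np.sqrt(1.0 - a) * e2

    ch1 = np.full(shape, background, dtype=float)
    ch2 = np.full(shape, background, dtype=float)
    ch1[fg] = base + sigma_tot * f1[fg]
    ch2[fg] = base + sigma_tot * f2[fg]
    if structure == "sheet":
        # dim background carries detector noise only (uncorrelated)
        bg = ~fg
        ch1[bg] += noise_sigma * rng.standard_normal(int(bg.sum()))
        ch2[bg] += noise_sigma * rng.standard_normal(int(bg.sum()))

    pair = ImagePair(ch1=ch1, ch2=ch2, roi_mask=fg if structure == "sheet" else None)
    gt = ColocGroundTruth(
        true_correlation=float(rho),
        foreground_mask=fg,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )
    return pair, gt


def one_phase(t, y0, plateau, k):
    """One-phase association curve Y(t) = Y0 + (Plateau - Y0)(1 - e^(-K t))."""
    t = np.asarray(t, dtype=float)
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def gen_frap_trace(gt: FrapGroundTruth) -> FrapTrace:
    """Generate one raw FRAP ROI trace plus reference trace from ground truth.

    Forward model (the inverse of the correction/normalization chain):

    * signal level S(t) = 1 pre-bleach, ``y0_true + (plateau_true -
      y0_true)(1 - e^(-rate_true t))`` post-bleach (t = 0 at the first
      post-bleach frame);
    * raw ROI   = background + scale * decay(t) * S(t) + noise,
    * raw ref   = background + scale * decay(t) + noise,

    where ``decay(t) = e^(-bleach_rate (t - t_first))`` models acquisition
    bleaching from the first acquired frame onward, and noise is additive
    Gaussian with standard deviation ``noise_sigma * scale``.

    The default timing matches the experimental protocol: three pre-bleach
    frames, then 10-s sampling for 10 minutes.
    """
    n_post = int(round(gt.duration / gt.interval)) + 1
    t_pre = -gt.interval * np.arange(gt.n_prebleach, 0, -1)
    t_post = gt.interval * np.arange(n_post)
    t = np.concatenate([t_pre, t_post])

    signal = np.ones_like(t)
    signal[gt.n_prebleach:] = one_phase(t_post, gt.y0_true, gt.plateau_true, gt.rate_true)

    decay = np.exp(-gt.bleach_rate * (t - t[0]))
    rng = np.random.default_rng(gt.seed)
    noise_roi = gt.noise_sigma * gt.scale * rng.standard_normal(len(t))
    noise_ref = gt.noise_sigma * gt.scale * rng.standard_normal(len(t))

    roi = gt.background + gt.scale * decay * signal + noise_roi
    ref = gt.background + gt.scale * decay + noise_ref
    return FrapTrace(
        t=t,
        roi=roi,
        ref=ref,
        background=gt.background,
        n_prebleach=gt.n_prebleach,
    )


def gen_follicle_series(
    n_timepoints=30,
    ratio_profile=None,
    depth_profile=None,
    noise_sigma=0.0,
    seed=0,
    interval_min=7.0,
    ife_level=100.0,
    two_ife_rois=True,
    movie_id="synthetic",
) -> FollicleSeries:
    """Generate a follicle intensity/depth time series with a programmed ratio.

    The follicle deepens over time (``depth_profile``, default linear 0 to
    40 um — a placode invaginating into a hair germ) and the follicle
    intensity is ``mean(IFE) * ratio_profile(depth) + noise``, so the
    programmed hair-follicle/IFE ratio as a function of depth is recovered
    exactly by the downstream ratio estimator when noise is zero.
    Timepoints are spaced ``interval_min`` (7 min default) apart.
    """
    if n_timepoints < 1:
        raise ArgumentError("n_timepoints must be >= 1")
    if ratio_profile is None:
        ratio_profile = lambda depth: 1.0 + depth / 50.0  # noqa: E731
    rng = np.random.default_rng(seed)
    t = interval_min * np.arange(n_timepoints)
    if depth_profile is None:
        depth = np.linspace(0.0, 40.0, n_timepoints)
    else:
        depth = np.asarray([depth_profile(ti) for ti in t], dtype=float)

    n_ife = 2 if two_ife_rois else 1
    ife = ife_level * (1.0 + 0.05 * rng.standard_normal((n_timepoints, n_ife)))
    ife_means = ife.mean(axis=1)
    hf = ife_means * np.asarray([ratio_profile(d) for d in depth], dtype=float)
    hf = hf + noise_sigma * rng.standard_normal(n_timepoints)
    return FollicleSeries(
        t=t,
        hf_intensity=hf,
        ife_intensities=[list(row) for row in ife],
        depth=depth,
        movie_id=movie_id,
    )


def _rotate(v, degrees):
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _phase_geometry(cell_id, phase, angle_deg, jitter, rng):
    """Construct a symmetric five-point annotation with exact vertex angles.

    V1/V2 sit on the basal line flanking the dividing cell; A is the
    dividing cell's basal center above the midpoint.  Each neighbor center
    B_i is placed so that the interior angle at V_i between the rays toward
    A and toward B_i is exactly ``angle_deg`` (the ray to B_i is the ray to
    A rotated outward by the target angle).  +y is basal (downward).
    """
    half = 45.0  # px, half-distance between the two basal vertices
    V1 = np.array([-half, 0.0])
    V2 = np.array([half, 0.0])
    A = np.array([0.0, -30.0])  # apical of the basal line
    L = 60.0
    u1 = (A - V1) / np.linalg.norm(A - V1)
    u2 = (A - V2) / np.linalg.norm(A - V2)
    # rotate away from the cell: clockwise at V1 (left), counter-clockwise at V2
    B1 = V1 + L * _rotate(u1, -angle_deg)
    B2 = V2 + L * _rotate(u2, angle_deg)
    pts = {"A": A, "B1": B1, "B2": B2, "V1": V1, "V2": V2}
    if jitter > 0:
        for k in pts:
            pts[k] = pts[k] + jitter * rng.standard_normal(2)
    return DivisionGeometry(cell_id=cell_id, phase=phase, **pts)


def gen_division_geometry(
    interphase_angle=175.0,
    pinch=25.0,
    jitter=0.0,
    seed=0,
    cell_id="cell",
):
    """Generate annotated point sets for one dividing cell across three phases.

    The noiseless vertex angles are ``interphase_angle`` at interphase,
    ``interphase_angle - pinch`` at metaphase (the BM pinches inward under
    the rounded cell) and back to ``interphase_angle`` at cytokinesis.
    ``jitter`` adds isotropic Gaussian positional noise (px) to every
    annotated point.

    Returns a dict mapping phase name to :class:`DivisionGeometry`.
    """
    if not 0.0 < interphase_angle <= 180.0:
        raise ArgumentError("interphase_angle must lie in (0, 180]")
    if not 0.0 <= pinch < interphase_angle:
        raise ArgumentError("pinch must lie in [0, interphase_angle)")
    rng = np.random.default_rng(seed)
    angles = {
        "interphase": interphase_angle,
        "metaphase": interphase_angle - pinch,
        "cytokinesis": interphase_angle,
    }
    return {
        phase: _phase_geometry(cell_id, phase, ang, jitter, rng)
        for phase, ang in angles.items()
    }
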