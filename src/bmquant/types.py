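"""Domain containers shared across the bmquant modules.

All containers are plain dataclasses over numpy arrays.  Rasters are
row-major 2-D float arrays with the origin at the top-left and 0-based
pixel indices; in sagittal views +y points basally (downward, toward the
dermis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ArgumentError

#: default pixel size (um/px) of the high-resolution colocalization images
DEFAULT_PIXEL_SIZE_UM = 0.09


@dataclass
class ImagePair:
    """Two co-registered single-plane intensity rasters plus optional ROI mask.

    Parameters
    ----------
    ch1, ch2
        2-D intensity rasters (arbitrary units), identical shape.
    roi_mask
        Optional boolean raster restricting every analysis to a region of
        interest; ``None`` means the full frame.
    pixel_size
        Physical pixel size in micrometres per pixel.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    roi_mask: Optional[np.ndarray] = None
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.ndim != 2 or self.ch2.ndim != 2:
            raise ArgumentError("channels must be 2-D rasters")
        if self.ch1.shape != self.ch2.shape:
            raise ArgumentError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.ch1.shape:
                raise ArgumentError(
                    f"roi_mask shape {self.roi_mask.shape} does not match "
                    f"channels {self.ch1.shape}"
                )
        if not self.pixel_size > 0:
            raise ArgumentError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def mask(self) -> np.ndarray:
        """Effective analysis mask (all-True when no ROI was given)."""
        if self.roi_mask is None:
            return np.ones(self.ch1.shape, dtype=bool)
        return self.roi_mask


@dataclass
class ColocGroundTruth:
    """Known truth behind a synthetic image pair."""

    true_correlation: float
    foreground_mask: np.ndarray
    noise_sigma: float
    seed: int

    def __post_init__(self):
        if not -1.0 <= self.true_correlation <= 1.0:
            raise ArgumentError(
                f"true_correlation must lie in [-1, 1], got {self.true_correlation}"
            )


@dataclass
class ColocResult:
    """Costes-thresholded Pearson analysis of one image pair.

    ``r`` is the Pearson coefficient over ROI pixels above threshold in
    either channel (the Coloc2 convention); ``r_all`` is the coefficient
    over every ROI pixel.  ``degenerate`` flags image pairs for which the
    Costes scan never decorrelates (perfectly colocalized limit) so the
    thresholds fell back to the channel minima.
    """

    r: float
    r_all: float
    t1: float
    t2: float
    slope: float
    intercept: float
    p_value: float
    n_randomizations: int
    degenerate: bool = False

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ArgumentError(f"r out of [-1, 1]: {self.r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ArgumentError(f"p_value out of (0, 1]: {self.p_value}")
        if self.n_randomizations < 1:
            raise ArgumentError("n_randomizations must be >= 1")


@dataclass
class OverlapResult:
    """Per-channel overlap fractions between two Otsu masks."""

    frac_ch1: float
    frac_ch2: float
    area_ch1: int
    area_ch2: int
    area_overlap: int

    def __post_init__(self):
        for name in ("frac_ch1", "frac_ch2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ArgumentError(f"{name} out of [0, 1]: {v}")
        if self.area_overlap > min(self.area_ch1, self.area_ch2):
            raise ArgumentError("overlap area exceeds a channel mask area")


@dataclass
class FrapGroundTruth:
    """Known truth behind a synthetic FRAP trace.

    The recovery is parameterised in the corrected-intensity domain
    relative to the pre-bleach level (=1): immediately after the bleach the
    signal sits at ``y0_true`` and recovers toward ``plateau_true`` with
    rate ``rate_true``.  The identifiable quantities after the
    normalization step are the rate and the mobile fraction
    ``(plateau_true - y0_true) / (1 - y0_true)``.
    """

    y0_true: float = 0.2
    plateau_true: float = 0.3
    rate_true: float = 0.01
    bleach_rate: float = 5e-4
    background: float = 50.0
    noise_sigma: float = 0.02
    n_prebleach: int = 3
    interval: float = 10.0
    duration: float = 600.0
    scale: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.y0_true <= self.plateau_true <= 1.0:
            raise ArgumentError(
                "require 0 <= y0_true <= plateau_true <= 1, got "
                f"y0={self.y0_true}, plateau={self.plateau_true}"
            )
        if not self.rate_true > 0:
            raise ArgumentError("rate_true must be positive")
        if self.n_prebleach < 1:
            raise ArgumentError("n_prebleach must be >= 1")
        if not self.interval > 0:
            raise ArgumentError("interval must be positive")
        if self.bleach_rate < 0:
            raise ArgumentError("bleach_rate must be non-negative")

    @property
    def mobile_true(self) -> float:
        """Mobile fraction implied by the generating parameters."""
        if self.y0_true >= 1.0:
            return 0.0
        return (self.plateau_true - self.y0_true) / (1.0 - self.y0_true)


@dataclass
class FrapTrace:
    """Timed ROI / reference / background intensities of one FRAP run.

    ``t`` is in seconds with t=0 at the first post-bleach frame (pre-bleach
    frames carry negative times); ``bleach_index`` equals ``n_prebleach``.
    """

    t: np.ndarray
    roi: np.ndarray
    ref: np.ndarray
    background: float
    n_prebleach: int
    bleach_index: int = None  # type: ignore[assignment]
    trace_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if self.bleach_index is None:
            self.bleach_index = self.n_prebleach
        if not (len(self.t) == len(self.roi) == len(self.ref)):
            raise ArgumentError("t, roi and ref must have equal length")
        if self.n_prebleach < 1:
            raise ArgumentError("n_prebleach must be >= 1")
        if self.bleach_index != self.n_prebleach:
            raise ArgumentError("bleach_index must equal n_prebleach")
        if self.bleach_index >= len(self.t):
            raise ArgumentError("trace has no post-bleach frames")
        if not np.all(np.diff(self.t) > 0):
            raise ArgumentError("t must be strictly increasing")


@dataclass
class FrapFit:
    """One-phase association fit of a normalized FRAP trace."""

    y0: float
    plateau: float
    k: float
    r2: float
    mobile_fraction: float
    immobile_fraction: float
    accepted: bool
    k_identifiable: bool = True
    trace_id: str = ""

    def __post_init__(self):
        if abs(self.mobile_fraction + self.immobile_fraction - 1.0) > 1e-12:
            raise ArgumentError("mobile_fraction + immobile_fraction must equal 1")


@dataclass
class FollicleSeries:
    """Per-timepoint hair-follicle intensity, IFE intensities and depth."""

    t: np.ndarray  # minutes
    hf_intensity: np.ndarray  # a.u.
    ife_intensities: list  # one or two a.u. values per timepoint
    depth: np.ndarray  # um below the IFE plane
    movie_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.hf_intensity = np.asarray(self.hf_intensity, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = len(self.t)
        if not (len(self.hf_intensity) == len(self.ife_intensities) == len(self.depth) == n):
            raise ArgumentError("all FollicleSeries fields must have equal length")
        for i, vals in enumerate(self.ife_intensities):
            if not 1 <= len(vals) <= 2:
                raise ArgumentError(
                    f"timepoint {i}: expected 1-2 IFE values, got {len(vals)}"
                )
        if np.any(self.depth < 0):
            raise ArgumentError("depth must be non-negative")


@dataclass
class DivisionGeometry:
    """Annotated 2-D points around one dividing basal cell at one phase.

    ``A`` is the basal-surface center of the dividing cell, ``B1``/``B2``
    the basal-surface centers of its two neighbors and ``V1``/``V2`` the
    basal-most intersections of the dividing cell with each neighbor — the
    vertices at which the deformation angles are measured.
    """

    cell_id: str
    phase: str  # interphase | metaphase | cytokinesis
    A: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    V1: np.ndarray
    V2: np.ndarray

    PHASES = ("interphase", "metaphase", "cytokinesis")

    def __post_init__(self):
        if self.phase not in self.PHASES:
            raise ArgumentError(f"unknown phase {self.phase!r}")
        for name in ("A", "B1", "B2", "V1", "V2"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ArgumentError(f"point {name} must be a finite 2-vector")
            setattr(self, name, p)
        for v, other in (("V1", "A"), ("V1", "B1"), ("V2", "A"), ("V2", "B2")):
            if np.allclose(getattr(self, v), getattr(self, other)):
                raise ArgumentError(f"points {v} and {other} coincide")
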