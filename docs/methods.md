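# Methods

`bmquant` quantifies three aspects of basement-membrane (BM) biology from
fluorescence imaging of an endogenously tagged collagen IV: how well two BM
components colocalize at pixel scale, how mobile tagged collagen IV is
(FRAP), and how the BM deforms during hair-follicle development and basal
cell division. Because the raw microscopy such pipelines consume is rarely
shareable, every estimator is paired with a seeded synthetic generator that
produces inputs with the true parameter programmed in; the test suite and
the acceptance script validate the estimators against those known truths.

## Colocalization

**Pearson r.** The product-moment correlation of the two channels'
intensities over the analysis ROI. It is invariant under positive affine
rescaling of either channel, so it is insensitive to gain/offset
differences between detectors.

**Costes automatic thresholds.** An orthogonal (total-least-squares)
regression of channel 2 on channel 1 is fitted over the ROI; candidate
thresholds `t1` walk down the unique sorted channel-1 values (exact — no
binning) with `t2 = slope*t1 + intercept`, and the procedure returns the
highest pair at which the pixels *below* both thresholds have `r <= 0`.
The reported coefficient is then computed over pixels above threshold in
either channel (the Coloc2 convention; the whole-ROI `r` is also emitted
since reports differ on which population they quote). Perfectly
colocalized inputs never decorrelate; such pairs are returned with the
channel minima and a `degenerate` flag rather than an error. Candidate
sets with fewer than two below-threshold pixels or a constant channel are
skipped.

**Randomization significance.** The observed `r` is compared with `n`
(default 100) surrogates in which `block x block` tiles of channel 2 over
the ROI bounding box are permuted — full tiles among themselves,
identically-shaped partial edge tiles among themselves. The default block
of 5 px approximates one optical resolution element at 0.09 um/px with
0.26 um resolution, so surrogates preserve local autocorrelation while
destroying cross-channel alignment. The p-value is the add-one estimator
`(1 + #{r_rand >= r_obs}) / (n + 1)`, one-sided toward colocalization, so
p is never zero and equals `1/(n+1)` for a perfectly colocalized pair.
For non-rectangular ROIs, tiles are permuted over the bounding box and
`r` is evaluated on ROI pixels only — pixels from outside the ROI can
enter it, the standard approximation in plugin implementations.

**Otsu masks and overlap fractions.** Each channel is thresholded by Otsu
over a 256-equal-width-bin histogram spanning the masked min–max (the
ImageJ dialect), with class statistics computed from exact per-bin pixel
sums and ties broken toward the lower threshold — the result is exactly
the exhaustive between-class-variance argmax over the 256 bin edges. The
overlap map is the AND of the two masks by default; a "product" dialect
(Otsu on the pixelwise product image, intersected with both masks) is
provided because macro pipelines sometimes re-threshold a combined overlap
image, and the composition of that step is ambiguous when the inputs are
already binary. Each overlap fraction is the overlap area divided by that
channel's mask area, so nested masks give (0.5, 1.0)-style asymmetric
readouts and the values swap under channel exchange.

## FRAP

A bleached circular ROI (1.5 um diameter in the experiments emulated), a
non-bleached reference ROI and a scalar background are processed as:

1. **Correction** — `corrected = (roi - background) / b(t)` with
   `b(t) = (ref - background) / mean_prebleach(ref - background)`.
   Ratiometric correction is exact under multiplicative acquisition
   bleaching: for noiseless synthetic traces any bleach rate yields output
   identical (to 1e-9) to the unbleached case. Negative corrected values
   are retained so the subsequent normalization remains affine.
2. **Normalization** — `(F_t - F_bleach) / (F_ini - F_bleach)`, with
   `F_ini` the mean of the pre-bleach frames (3 by default) and `F_bleach`
   the single frame immediately after bleaching (not a minimum over
   frames). The bleach frame maps exactly to 0 and the pre-bleach mean
   exactly to 1.
3. **Fitting** — least squares of the one-phase association
   `Y(t) = Y0 + (Plateau - Y0)(1 - e^(-K t))` on post-bleach points
   (t = 0 at the first post-bleach frame), initialized from the first
   point, the mean of the last five points, and `ln 2 / t_half`, with
   `K > 0` bounded. Fits with `r² <= 0.9` are retained but flagged
   `accepted=false` and excluded from pooling. A flat trace returns
   `plateau = y0` with the rate flagged unidentifiable instead of failing.
4. **Fractions** — `immobile = 1 - (Plateau - Y0)/(1 - Y0)`;
   `mobile = 1 - immobile` exactly.

An identifiability note: because the normalization pins the bleach frame
to 0, the physical bleach depth is not recoverable from a normalized
trace — any trace whose underlying recovery runs from depth `y0` to
plateau `P` normalizes to the one-phase curve with intercept 0, plateau
`(P - y0)/(1 - y0)` (the mobile fraction) and the same rate. Round-trip
tests therefore assert exact recovery of the rate and the mobile/immobile
fraction (the quantities the analysis reports), not of the generator's
internal bleach depth. With the immobile-fraction formula above, a fitted
intercept of 0 makes `immobile = 1 - Plateau`, which is how a fitted
plateau of 0.12 reads as a mobile fraction of 12%.

`register_xy` provides integer-pixel translation alignment of a raster
time series to its first frame (phase cross-correlation), reporting
per-frame drifts; sub-pixel registration and axial drift are out of scope
(axial stability is a precondition of trace extraction).

`pool_curves` averages normalized curves on a common time grid (pointwise
mean, sample SD, n). Pooling of traces rather than of fitted parameters is
the default presentation; per-trace fits are always emitted alongside, so
either summary can be derived.

## Morphometry

**Follicle/IFE ratio.** Per timepoint, the hair-follicle ROI mean divided
by the mean of one or two interfollicular-epidermis (IFE) ROI means. The
ratio is invariant under global intensity gain.

**Stage binning.** All depth measurements (follicle base below the IFE
plane, um) across movies are median-split: shallower half "placode",
deeper half "hair germ", sizes within one of each other (odd counts favor
placode), ties resolved by stable input order.

**IFE background ratio.** Each individual IFE measurement divided by its
movie's mean IFE value; per movie the ratios average to 1 exactly, making
movies comparable.

**Division deformation angles.** Five annotated points per dividing cell
and phase: the dividing cell's basal center A, the neighbors' basal
centers B1/B2, and the basal-most intersections V1/V2 with each neighbor.
The BM angle on each side is the interior angle at V_i between the rays
toward A and toward B_i (in [0, 180] degrees); the cell's value is the
mean of the two sides. Angles are invariant under rigid motion, uniform
scaling and mirror reflection of the annotation. Per cell, phases are
normalized to the interphase angle as a signed difference in degrees
(metaphase deformation is negative when the BM pinches inward); a ratio
dialect is available. The difference scale is the primary output because
the biological claim of interest — a mean inward pinch of ~25 degrees
under metaphase rounding — is a difference-scale statement. Annotation
conventions: row-major rasters, origin top-left, +y basal (downward) in
sagittal views. Mitotic phases are taken from explicit annotations, not
inferred from timing.

**Group statistics.** Two groups: two-sided Mann-Whitney U, exact when
both n <= 8 without ties, otherwise the tie-corrected normal
approximation. Several groups: Kruskal-Wallis omnibus followed by Dunn's
pairwise z-tests on pooled mean ranks with the pooled tie correction;
Dunn's test canonically follows Kruskal-Wallis, so the nonparametric chain
is the default and a parametric one-way ANOVA omnibus is available as an
option. The multiple-comparison adjustment (Bonferroni default, Holm
optional) is a configuration choice reported in the output. Dunn's test is
implemented in-package from the standard rank formula since no installed
library provides it; it is validated against hand-computed statistics and
by type-I-error calibration.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` with one
explicit integer seed per call and no global state; identical arguments
give bit-identical output.

* **Image pairs** — within the foreground, both channels fluctuate around
  a common base level with draws from an exact bivariate normal of
  correlation `rho`, built by mixing a shared latent field with
  independent fields; detector noise (`noise_sigma`, additive Gaussian)
  contributes to the independent component, so the programmed correlation
  accounts for it and the sample r is calibrated to within `3/sqrt(n)` of
  `rho`. The "sheet" structure confines the foreground to a ~5 px
  sinusoidal band (a thin undulating BM in a sagittal view) with constant
  base level inside the band, keeping the within-band correlation exactly
  `rho`; the surrounding background is dim with independent noise. No
  point-spread-function or 3-D optics are modeled: the generator tests
  estimators, not microscopes.
* **FRAP traces** — the inverse of the correction/normalization chain:
  `roi = background + scale*decay(t)*S(t) + noise` and
  `ref = background + scale*decay(t) + noise`, with `S` the one-phase
  recovery (1 pre-bleach) and `decay` single-exponential acquisition
  bleaching from the first acquired frame. Defaults follow the emulated
  protocol: 3 pre-bleach frames, 10-s intervals, 10-min monitoring,
  bleach depth 0.2, acquisition bleaching 5e-4/s, noise sigma 0.02 of the
  pre-bleach level. Photophysics beyond single-exponential acquisition
  bleaching (blinking, reversible photoswitching, diffusion during the
  bleach) is not modeled, so parameter-recovery results bound estimator
  error, not biological-model error.
* **Follicle series** — 7-min frame spacing; follicle intensity is
  `mean(IFE) * ratio_profile(depth) + noise` over a deepening follicle
  (default: linear 0–40 um, ratio 1 + depth/50), so the programmed
  depth–ratio relation is exactly recoverable.
* **Division geometries** — a symmetric basal construction (vertices
  90 px apart, neighbor rays 60 px — scaled to typical high-zoom
  annotation distances) in which each neighbor ray is the ray toward the
  dividing cell rotated outward by exactly the target angle, giving exact
  noiseless vertex angles of `interphase_angle`, `interphase_angle -
  pinch`, and `interphase_angle` across the three phases; `jitter` adds
  isotropic Gaussian positional noise to every point. Because the vertex
  angle is a nonlinear function of the points, jittered angle estimates
  carry a small curvature bias (about -0.1 degree at 1-px jitter at this
  geometry scale), well inside the 2-standard-error recovery band used in
  validation.

## Numerical and design notes

* Thresholds, fits and p-values are deterministic given the inputs and
  the seed; every CLI run embeds its config snapshot, seed and package
  version in the JSON output, so results are reproducible from the output
  alone.
* Degenerate inputs fail loudly: constant channels, empty ROIs/masks,
  reference-equals-background frames and traces without a detectable
  bleach raise typed errors naming the offending frame/column where
  applicable; the two intentional soft paths are the degenerate Costes
  flag and the unidentifiable-rate flag on flat FRAP traces.
* Validation problem sizes (e.g. 200 traces per FRAP condition, 500 null
  pairs for randomization calibration at 40x40 px, 50 jittered cells)
  were chosen to give standard errors comfortably below the tolerances
  being checked while keeping the full suite fast on a laptop.

## Limitations

* Cell segmentation, tracking, ROI drawing and mitotic-phase detection
  are out of scope; all region and point annotations are inputs.
* Colocalization is strictly 2-D and single-plane; Manders coefficients
  beyond the area-fraction definition are not provided.
* The FRAP model is a single-exponential association; reaction–diffusion
  and multi-component recoveries are not fitted.
* The synthetic image model omits optics (PSF, pixel saturation, Poisson
  statistics by default), so calibration results demonstrate estimator
  correctness on the stated noise model, not performance on real
  micrographs.
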