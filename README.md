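# bmquant

Quantification toolkit for fluorescence imaging of basement membranes
(BMs) — the thin collagen-IV-rich extracellular-matrix sheets underlying
epithelia. It is aimed at imaging labs working with endogenously tagged BM
components (e.g. a fluorescently tagged collagen IV allele in embryonic
skin) who need reproducible, scriptable versions of three common
quantifications that are usually done with ad-hoc ImageJ macros and
spreadsheets:

* **Colocalization** of two BM components at pixel scale: Pearson r with
  Costes automatic thresholding, block-randomization significance, and
  Otsu-mask overlap fractions.
* **FRAP** (fluorescence recovery after photobleaching) of a tagged BM
  protein: background subtraction, ratiometric acquisition-bleaching
  correction, normalization, one-phase association fitting and
  mobile/immobile fractions.
* **Live-imaging morphometry**: hair-follicle / interfollicular-epidermis
  (IFE) intensity ratios with developmental-stage binning, and BM
  deformation angles around dividing basal cells.

A seeded synthetic-data generator produces ground-truthed inputs for every
stage (image pairs with a known pixel correlation, FRAP traces with known
kinetics, follicle series and annotated division geometries), so the whole
pipeline is testable without any raw microscopy.

## The statistics at the core

**Costes-thresholded Pearson.** For channels $(X, Y)$ over an ROI, an
orthogonal regression $Y = aX + b$ sets candidate threshold pairs
$(t_1,\, a t_1 + b)$; scanning $t_1$ down from $\max X$, the chosen
thresholds are the highest at which the sub-threshold pixels satisfy
$r(X_{<t_1}, Y_{<t_2}) \le 0$. The reported $r$ is over pixels above
threshold in either channel. Significance: $p = (1 + \#\{r_\text{rand}
\ge r_\text{obs}\})/(n+1)$ over $n$ spatial block permutations of $Y$
(default $n = 100$, 5-px blocks).

**Overlap fractions.** With per-channel Otsu masks $M_1, M_2$ (256-bin
histogram dialect) and overlap $M_1 \cap M_2$:
$f_i = |M_1 \cap M_2| / |M_i|$.

**FRAP.** Corrected traces are normalized as
$(F_t - F_\text{bleach})/(F_\text{ini} - F_\text{bleach})$ and fitted to
the one-phase association $Y(t) = Y_0 + (P - Y_0)(1 - e^{-Kt})$; the
immobile fraction is $1 - (P - Y_0)/(1 - Y_0)$, with fits gated at
$r^2 > 0.9$.

**Deformation angles.** At each basal vertex $V_i$ flanking a dividing
cell, the interior angle between the rays $V_i \to A$ (dividing cell's
basal center) and $V_i \to B_i$ (neighbor's basal center); per cell, the
mean of both sides, normalized to the interphase angle.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from bmquant import synthetic, coloc, frap, morphometry
from bmquant.types import FrapGroundTruth

# --- colocalization on a synthetic BM-like sheet with true rho = 0.8
pair, truth = synthetic.gen_correlated_pair(
    shape=(128, 128), rho=0.8, structure="sheet", seed=42)
res = coloc.coloc_analysis(pair, n_rand=100, block=5, seed=42)
ov = coloc.overlap_fraction(pair)

# --- FRAP: near-immobile protein (true mobile fraction 12%)
gt = FrapGroundTruth(y0_true=0.2, plateau_true=0.296, rate_true=0.01,
                     noise_sigma=0.02, seed=42)
t, y = frap.process_trace(synthetic.gen_frap_trace(gt))
fit = frap.fit_one_phase(t, y)

# --- division-geometry pinch (true 25 degrees, 1-px annotation jitter)
phases = synthetic.gen_division_geometry(
    interphase_angle=175, pinch=25, jitter=1.0, seed=42)
inter, _ = morphometry.division_angles(phases["interphase"])
meta, _ = morphometry.division_angles(phases["metaphase"])
```

Output:

```
Pearson r (above Costes thresholds): 0.796
Pearson r (whole ROI):               0.802  (truth 0.8)
randomization p-value:               0.0099
overlap fractions: ch1 0.81, ch2 0.82
fitted K = 0.0121/s, mobile = 0.136, immobile = 0.864 (true mobile 0.12)
interphase 175.5 deg, metaphase 151.9 deg -> pinch 23.6 deg
```

Reading it: the whole-ROI Pearson r recovers the programmed correlation
to sampling error; the p-value is the minimum attainable with 100
randomizations (1/101), i.e. no spatial shuffle matched the observed
correlation. The FRAP fit reads a single noisy trace of a near-immobile
protein as 86% immobile (truth 88%), and the annotated division geometry
yields an inward metaphase pinch of ~24 degrees against a programmed 25.

## Command line

Every step is also available as a CLI with reproducible, seeded runs; the
JSON outputs embed the config snapshot, seed and package version.

```sh
bmquant --seed 7 simulate coloc --rho 0.8 --structure sheet --out pair.tif
bmquant --seed 7 coloc --in pair.tif --mask pair.mask.tif --n-rand 100 --out coloc.json
bmquant --seed 7 simulate frap --n-traces 30 --out traces/
bmquant --seed 7 frap fit --traces traces/ --background 50 --out fits.csv --pool pooled.csv
bmquant --seed 7 simulate division --pinch 25 --jitter 1 --out points.csv
bmquant morpho division --in points.csv --out angles.csv
bmquant stats --in groups.csv --design multi_group --out stats.json
```

CSV schemas are documented in `bmquant/io.py` (FRAP traces:
`time_s, roi_mean, ref_mean`; follicle series: `movie_id, t_min, hf_mean,
ife_mean_1, ife_mean_2, depth_um`; division points: `cell_id, phase,
role, x_px, y_px, frame`).

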