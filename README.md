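# rgcspatial

Analysis pipeline for **nonlinear spatial integration in retinal ganglion
cells (RGCs) responding to flashed natural images**, together with a
generative subunit-model retina that lets every stage be validated against
ground truth without recorded data.

Most RGCs do not sum light linearly over their receptive field (RF): input
from bipolar-cell–scale subunits is often rectified before pooling, so two
images with the same mean luminance in the RF can evoke very different
spike counts depending on their internal spatial structure. This package
implements the analyses that quantify that phenomenon and ties them
together across stimulus families:

* **RF estimation** — spike-triggered average (STA) from binary
  checkerboard white noise and a parametric fit
  `kS(x)·kT(t)` with a difference-of-Gaussians spatial profile
  `kS(x) = N(x; μ, Σ) − A_S·N(x; μ, κ²Σ)` and a difference-of-low-pass
  temporal filter
  `kT(t) = p1 ((t/τ1) e^{−t/τ1+1})^n − p2 ((t/τ2) e^{−t/τ2+1})^n`.
  The RF-center diameter is that of the circle matching the 2σ ellipse,
  `d = 4·(det Σ)^{1/4}`.
* **LN model** — spike-count prediction `R_m = f(k·s_m)` for flashed
  natural images, with a bi-logistic output nonlinearity and performance
  scored by the noise-normalized correlation
  `CCnorm = Cov(y, ŷ)/√(Var(ŷ)·SP)` under 10-fold cross-validation, where
  `SP` is the signal power estimated from trial-to-trial variability.
* **Spatial-contrast (SC) sensitivity** — the Gaussian-weighted SD of
  pixel contrasts inside the RF-center 2σ ellipse, and the regression of
  within-pair response differences on SC differences for
  linear-prediction-matched image pairs.
* **Gratings** — contrast-reversing (and flashed) square-wave gratings:
  logistic spatial scale of the peak-rate profile and the frequency-
  doubling nonlinearity index `F2_max/F1_max`.
* **Checkerboard flashes** — iso-response analysis over the two-tile
  contrast plane `(s_A, s_B)`: rectification index
  `RI = Σ wᵢ·r_oppos,i / Σ wᵢ·r_half,i` (0 = linear, 1 = fully
  rectified), convexity index `CI = 1 − Σ wᵢ·r_same,i / Σ wᵢ·r_half,i`
  (0 = linear, > 0 convex, < 0 homogeneity-preferring), relative
  sensitivity `(w_B − w_A)/(w_B + w_A)`, and iso-response contours.
* **Blur scale** — the logistic midpoint of response similarity (R²)
  versus Gaussian blur scale: the spatial scale of natural structure a
  cell's response depends on.
* **Cell classes** — image-recurrence-sensitive (IRS), direction- (DS)
  and orientation-selective (OS) cells via RSI, DSI/OSI with permutation
  tests, ON/OFF labels from the temporal filter, and 2-means clustering
  of OFF-OS cells into linear/nonlinear groups.
* **Synthetic retina** — `SubunitCell`: a grid of small Gaussian subunits
  with a configurable local nonlinearity (linear, half-wave rectified,
  partially rectified with strength λ, threshold-quadratic,
  homogeneity-preferring), Gaussian pooling matched to a target RF, a
  logistic output stage and Poisson spiking; plus generators for every
  stimulus protocol (natural-like 1/f images with nonstationary local
  contrast, white noise, gratings, checkerboard flashes, blur series,
  drifting gratings, saccade-like grating shifts).

## Worked example

```python
import numpy as np
from rgcspatial.checkerboard import (ContrastPairSurface,
                                     rectification_index, convexity_index)
from rgcspatial.synthetic import make_phenotype, simulate_checkerboard_surface

for name in ("linear_on", "rectified_on", "homogeneity_detector"):
    cell = make_phenotype(name)
    design, mu = simulate_checkerboard_surface(cell, noiseless=True)
    s = ContrastPairSurface(design, mu)
    print(f"{name:22s} RI={rectification_index(s):+.3f} "
          f"CI={convexity_index(s):+.3f}")
```

prints

```
linear_on              RI=-0.001 CI=-0.001
rectified_on           RI=+0.993 CI=-0.001
homogeneity_detector   RI=-0.157 CI=-0.519
```

A cell that integrates linearly treats an opposing-contrast checkerboard
as a null stimulus (RI = 0) and a homogeneous half-contrast flash as
equivalent to a single-component flash (CI = 0); half-wave-rectified
subunits respond equally to both configurations (RI = 1); a
homogeneity-preferring cell responds more to the homogeneous stimulus
(CI < 0).

The numbered drivers under `analysis/` run the full study on the
synthetic retina and write tidy tables under `results/`:

```bash
python analysis/01_phenotype_signatures.py   # iso-response signatures
python analysis/02_rf_recovery.py            # STA -> parametric-fit recovery
python analysis/03_cross_stimulus_cohort.py  # 60-cell cross-stimulus cohort
python analysis/04_cell_classes.py           # DS/OS/IRS detection
```

The cohort driver reproduces the study's headline structure: SC
sensitivity rises with the rectification index (Spearman ρ ≈ 0.95), LN
performance falls with it (ρ ≈ −0.45), performance rises with the blur
spatial scale (ρ ≈ 0.6–0.8), and the grating spatial scale is the
poorest predictor of LN performance.

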