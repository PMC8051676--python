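# Methods

This note documents the models, estimators and numerical choices behind
`rgcspatial`, and what the synthetic retina does and does not emulate.

## Receptive-field model and fit

The RF is space–time separable, `kS(x)·kT(t)`. Both spatial Gaussians are
unnormalized (peak 1), so the overall gain lives in the temporal
amplitudes `p1, p2`; at the center, `kS(μ) = 1 − A_S`. Constraints:
`A_S ∈ [0, 1]`, `κ ≥ 1`, all temporal parameters positive. For an OFF
cell the spatial center peak stays positive by convention and the sign is
carried by `kT` (the subtracted lobe peaks first).

Fitting is staged, then joint: the spatial profile is fitted to the STA
frame containing the largest-absolute element (sign-flipped if that
element is negative), the temporal profile to that element's time course,
and the joint model refined with bound-constrained L-BFGS-B
(`ftol = 1e-15`) from three jittered restarts, keeping the best and
stopping early once the residual reaches the numerical floor. The width
initialization uses the half-max region of the peak frame (semi-axes
`√(2 ln 2)·σ`), which is robust to background noise; a simple thresholded
second moment is biased low and can strand the optimizer in a local
minimum. An STA whose peak does not exceed 5 robust SDs of its entries is
rejected as unfittable.

On noiseless synthetic STAs (16×16 stixels of 60 µm, 15 lags at 30 Hz)
the fit recovers μ, Σ, `A_S`, τ1, τ2 to well under 1%; at SNR 10 the
center diameter stays within 10%.

## LN model and CCnorm

Images are normalized to mean = background, SD = 40% of the mean, clipped
at ±100% Weber contrast and quantized to 8 bits (quantization applied at
the contrast stage, emulating the display path; tests can disable it).
The spatial filter is the fitted `kS` sampled at the pixel centers of the
smallest square crop containing the RF center's 4σ box, L1-normalized.
The bi-logistic output
`f(g) = b + (M_ON−b)/(1+e^{−r_ON(g−g_ON)}) + (M_OFF−b)/(1+e^{r_OFF(g−g_OFF)})`
is fitted by trust-region least squares with box constraints; it is
initialized from a single-logistic fit describing the dominant lobe, with
the secondary lobe given a small nonzero amplitude and slope — a lobe
initialized with zero amplitude *and* zero slope has vanishing gradient
and U-shaped (ON-OFF) tuning would never be found.

Signal power is the printed estimator
`SP = [Var(Σ_n R_mn) − Σ_n Var(R_mn)] / (N(N−1))` with population
variances across images. For noiseless trials this reduces to exactly
`Var(y)` (the N² and N terms cancel to N(N−1)), so a perfect model's
CCnorm is exactly 1. Cross-validation uses a seeded random partition into
10 folds; each fold's CCnorm is computed entirely on the held-out images
(including its SP), folds with SP ≤ 0 are dropped with a warning, and the
reported performance is the fold mean. Small-fold SP estimates are noisy;
an occasional inflated fold value is tolerated because every downstream
use of CCnorm here is rank-based.

## Spatial contrast and its sensitivity

SC is the weighted SD of pixel contrasts with weights equal to the center
Gaussian at the pixel center, over pixels whose centers satisfy
`(x−μ)ᵀΣ⁻¹(x−μ) ≤ 4`. Pairing for the sensitivity slope sorts images by
the linear prediction g (ties broken by image id), pairs consecutive
images, and takes within-pair differences as higher-SC minus lower-SC
member, so a positive slope means structure boosts the response.
Difference responses are normalized by the cell's maximum trial-mean
response over all images. The slope test is ordinary least squares with
the conventional two-sided t-test at α = 0.05; its type-I error is
calibrated within [0.5×, 2×] of nominal over 1000 null simulations.

Blurring is *mostly* a contraction on SC: pointwise exceptions occur for
near-flat RF patches into which blur smears structure from outside the 2σ
contour; the aggregate (mean over images) always decreases.

## Gratings

PSTHs use 10 ms bins, averaged over repeats with the first reversal after
a gray period excluded. One analysis period spans a full stimulus cycle —
two contrast reversals (2 s at 1 s reversal intervals), or the 400 ms
concatenation of the two 200 ms flashes in the flashed variant — so F1
(one modulation per cycle) and F2 (two per cycle) are the PSTH's first
and second discrete Fourier amplitudes, `2|X_k|/n`. F1 and F2 maxima are
taken over all bar widths and phases independently; the ratio is
normalization-free. The spatial scale is the midpoint of a logistic
fitted to peak rate versus log bar width (the widths span two-plus
decades once the homogeneous-illumination condition, treated as the
largest width, is included; a linear-width fit with that anchor is
numerically ill-behaved). The midpoint is constrained to
[half the smallest width, 2× the largest finite width]; profiles that are
flat, or whose midpoint pins at a bound, are flagged unresolved.

## Checkerboard-flash iso-response analysis

The design is polar: 24 equidistant angles × 10 radii between 3% and
100% contrast, plus the (0,0) blank presented as a regular stimulus.
Responses at required but unsampled pairs — (c, −c) at radius ≈ 0.849 for
c = 0.6, and (c/2, c/2) — are estimated with a C1 Clough–Tocher
scattered-data interpolant (exact at samples, continuous in the hull,
reproduces linear fields to machine precision), with a nearest-sample
fallback outside the hull. Half-axis weights `wᵢ` are OLS slopes of
background-subtracted response versus contrast along each half-axis; the
two opposing-contrast responses are each assigned to the two half-axes
they border, and the two homogeneous responses likewise. RI and CI are
invariant to positive rescaling and offsets of the response, which is the
point of the iso-response construction: contour geometry is untouched by
any monotone output nonlinearity. Contours are extracted by marching
squares on a 201×201 rasterization of the interpolated surface, with the
region outside the sampled contrast disk masked so contours terminate at
the data boundary. The secondary contrast level c = 0.3 is available for
robustness checks.

## Blur scale

Blur scales are expressed as the 2σ-contour diameter of the blurring
Gaussian (scale = 4σ), matching the RF-diameter convention; convolution
uses reflective padding. The similarity curve assigns the odd/even-trial
R² of the original responses to scale 0 and the symmetrized R² between
blurred and original trial means to each positive scale. The default
ladder is {30, 60, 120, 240, 480, 960} µm: with a ladder ending at 480 µm
the logistic midpoint is unidentifiable for cells whose similarity has
not decayed within range, and the estimate collapses to the middle of the
sampled interval. The logistic is fitted on R² clipped to [0, 1.05]
(matching the asymptote constraints; strongly negative R² means "no
similarity" and carries no extra information).

## Cell classes

RSI uses the maximal successive-bin PSTH increase in the 50–200 ms
post-fixation window; positions two phases apart are contrast-reversed
partners. The IRS criterion is RSI > 0.7 and a mean peak rate of the four
recurrence PSTHs ≥ 50 Hz (mean over each PSTH's maximum bin). DSI/OSI are
the magnitudes of the normalized complex sums with angle and doubled
angle; significance is a 2000-shuffle permutation test over all angles
and trials with the add-one estimator (a vectorized variant evaluates all
shuffles as one matrix product for calibration studies). Classification
thresholds: DSI/OSI > 0.25, p < 0.01, mean rate > 1 Hz; OS excludes DS
and IRS cells. ON/OFF labels take the sign of the first temporal-filter
extremum whose unsigned amplitude reaches 25% of the largest deflection.
OFF-OS clustering is 2-means with 20 seeded restarts on z-scored
(CCnorm, SC slope, RI, CI); incomplete cells are assigned by nearest
centroid on their available standardized coordinates, and the cluster
with the higher mean CCnorm is named "linear".

## The synthetic retina

`SubunitCell` pools a square grid of Gaussian subunits (default spacing
60 µm, σ = 10 µm, i.e. a ~40 µm 4σ diameter at the small end of the
bipolar range) with Gaussian weights matched to a target RF center, and
maps the pooled drive through a logistic output (baseline 0.2, maximum 16
spikes per 250 ms window ≈ 64 Hz peak, midpoint 0.2, slope 10) to an
expected count; trial counts are Poisson. The operating point is chosen
so cells across the RF-size range actually use their dynamic range for
natural images — with a high fixed midpoint, large-RF cells (whose pooled
drives are compressed toward zero) are nearly silent and every
reliability-based analysis starves. The subunit grid is offset 30 µm from
checkerboard tile borders; with larger subunits or border-straddling
grids, tile mixing drags the fully rectified cell's RI below 1 as a
geometry artifact.

Local nonlinearities: linear; half-wave rectified; partially rectified
`n(u) = u` for `u > 0`, `(1−λ)u` otherwise (λ = 0 linear, λ = 1
rectified); threshold-quadratic; and homogeneity-preferring
`n(u) = u − β u²` (β = 0.8) — a compressive penalty on local contrast
magnitude that yields RI < 0 and CI < 0, the observed signature, where a
common-mode expansive pathway would not (it leaves the half-contrast and
homogeneous stimuli with identical pooled drives). ON-OFF variants use
full-wave local rectification or a U-shaped output, both with the OFF
side at 60% of the ON side: a perfectly balanced ON-OFF cell has an
exactly symmetric grating response and therefore F1 = 0, which makes
F2/F1 degenerate and is not observed in real populations.

Natural-like images are Gaussian random fields with a 1/f² power
spectrum, multiplied by a smooth log-normal local-contrast envelope
(strength 1.5, correlation scale 150 µm) before display normalization.
The envelope is essential: a *stationary* Gaussian field has nearly the
same within-RF contrast in every image, so a rectified cell's response
remains an almost exact function of the linear prediction and the
LN-performance deficit the analysis is built to detect would barely
exist. What the generator does not emulate: occlusion edges, heavy-tailed
wavelet statistics, object structure, and luminance–contrast correlations
of real scenes. Passing tests therefore demonstrate that the estimators
recover planted structure of this model class, not that real RGCs behave
this way.

Grating responses are modeled quasi-sustainedly: each subunit's drive is
carried at the reversal fundamental, `u_j(t) = d_j sin(2πt/T)`, pooled
through the local nonlinearity, and passed through a logistic centered on
the cycle mean (contrast adaptation to a periodic stimulus). A linear
cell's modulation is then odd-symmetric with zero even harmonics, and
frequency doubling arises only from subunit rectification. Gratings are
tilted 22.5° relative to the subunit mosaic: an axis-aligned square wave
commensurate with the regular model grid makes even a linear cell appear
sensitive to fine bars, an artifact a jittered biological mosaic never
shows. Saccade and drifting-grating responses are generated directly as
rate profiles with the planted tuning (transients on recurrence, cosine
or cos² direction tuning) plus Poisson spiking — planted-parameter
generators, not circuit models.

## Cohort used for the cross-stimulus analysis

Sixty cells: a λ-grid of partially rectifying ON cells plus one-sixth
each full-wave ON-OFF and U-shaped-output ON-OFF cells; RF-center σ drawn
uniformly from 35–120 µm (diameters ≈ 140–480 µm) and subunit σ from
8–25 µm (ON-OFF cells 15–35 µm, reflecting their coarser nonlinear
units). Stimulus sizes follow the experimental protocol (300 images ×
10 trials, 200 ms flashes with a 250 ms count window; full checkerboard
design; 5 bar widths 15–240 µm plus homogeneous reversals; 6 blur
scales). The run takes about four minutes on one core.

## Known limitations

* The simulator's RF surround is off by default; surround-mediated
  effects on the indices are untested.
* Natural-image responses are count-level; no within-window dynamics.
* The grating temporal model is a single-harmonic caricature; absolute
  F1/F2 values are not comparable to recordings, only their ordering.
* Local (patch-based) checkerboard analysis shares the full-field code
  path; patch placement is supported but the interaction with surrounds
  is not modeled.
* The deposited-recording filter counts require the archive download and
  are not recomputed here; the inclusion filters themselves are tested on
  synthetic cohorts.
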