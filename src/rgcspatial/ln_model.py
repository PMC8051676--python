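"""Linear-nonlinear model of flashed-natural-image responses.

The model predicts a cell's trial-averaged spike count to image m as
R_m = f(k^T s_m): the image, expressed in Weber contrast and clipped to the
square containing the 4-sigma boundary of the RF center, is projected onto
the L1-normalized parametric spatial filter, and the scalar "linear
prediction" g_m is mapped through a bi-logistic output nonlinearity

  f(g) = b + (M_ON - b) / (1 + exp(-r_ON (g - g_ON)))
       + (M_OFF - b) / (1 + exp( r_OFF (g - g_OFF)))

which can describe monotone (ON or OFF) as well as U-shaped (ON-OFF) tuning.
Performance is the noise-normalized correlation CCnorm = Cov(y, yhat) /
sqrt(Var(yhat) * SP), averaged over 10 cross-validation folds, where SP is
the signal power estimated from trial-to-trial variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_data import TrialResponseTable
from .rf_estimation import ParametricRF, eval_spatial_dog, rf_center_diameter

__all__ = [
    "BiLogistic",
    "LNModelFit",
    "preprocess_image",
    "clip_to_rf",
    "linear_prediction",
    "fit_single_logistic",
    "fit_bilogistic",
    "signal_power",
    "cc_norm",
    "crossvalidate_ln",
    "logistic",
]

PIXEL_SIZE_UM = 7.5  # display pixel side on the retina


def logistic(x, b, m, r, x0):
    """Single logistic b + (m - b) / (1 + exp(-r (x - x0)))."""
    return b + (m - b) / (1.0 + np.exp(-r * (x - x0)))


@dataclass
class BiLogistic:
    b: float
    m_on: float
    m_off: float
    r_on: float
    r_off: float
    g_on: float
    g_off: float

    def __call__(self, g):
        g = np.asarray(g, dtype=float)
        on = (self.m_on - self.b) / (1.0 + np.exp(-self.r_on * (g - self.g_on)))
        off = (self.m_off - self.b) / (1.0 + np.exp(self.r_off * (g - self.g_off)))
        return self.b + on + off


@dataclass
class LNModelFit:
    spatial_filter: np.ndarray  # L1-normalized, over clipped-image pixels
    nonlinearity: BiLogistic | None
    cc_norm: float
    cc_norm_per_fold: np.ndarray
    linear_predictions: np.ndarray = field(default=None)


def preprocess_image(
    raw: np.ndarray, background: float, quantize: bool = True
) -> np.ndarray:
    """Normalize an intensity image and convert to clipped Weber contrast.

    The image is shifted/scaled so its mean equals the background intensity
    and its SD equals 40% of that mean; values deviating from the mean by
    more than 100% are clipped, and the result is encoded at 8-bit depth
    (256 levels spanning [-1, 1]), emulating the display path.
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("constant image cannot be normalized")
    z = (raw - raw.mean()) / sd
    intensity = background + 0.4 * background * z
    contrast = (intensity - background) / background
    contrast = np.clip(contrast, -1.0, 1.0)
    if quantize:
        levels = np.round((contrast + 1.0) / 2.0 * 255.0)
        contrast = levels / 255.0 * 2.0 - 1.0
    return contrast


def clip_to_rf(
    image: np.ndarray, rf: ParametricRF, pixel_size: float = PIXEL_SIZE_UM
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Crop to the smallest square covering the RF center's 4-sigma box.

    Returns (s, k, (row0, col0)): the flattened contrast vector of the crop,
    the matched L1-normalized spatial filter (the difference-of-Gaussians
    profile sampled at pixel centers), and the crop origin in pixel indices.
    """
    ny, nx = image.shape
    mu = rf.center_mean
    evals = np.linalg.eigvalsh(rf.center_cov)
    half = 4.0 * np.sqrt(evals.max())  # 4-sigma along the major axis
    side = int(np.ceil(2.0 * half / pixel_size))
    cx = int(round(mu[0] / pixel_size - 0.5))
    cy = int(round(mu[1] / pixel_size - 0.5))
    col0 = cx - side // 2
    row0 = cy - side // 2
    if col0 < 0 or row0 < 0 or col0 + side > nx or row0 + side > ny:
        warnings.warn("4-sigma box exceeds image bounds; crop truncated", stacklevel=2)
        col0 = max(col0, 0)
        row0 = max(row0, 0)
        side = min(side, nx - col0, ny - row0)
    crop = image[row0 : row0 + side, col0 : col0 + side]

    xs = (np.arange(col0, col0 + side) + 0.5) * pixel_size
    ys = (np.arange(row0, row0 + side) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    k = eval_spatial_dog(rf, np.stack([xx, yy], axis=-1))
    k = k / np.abs(k).sum()
    return crop.ravel(), k.ravel(), (row0, col0)


def linear_prediction(k: np.ndarray, s: np.ndarray) -> float:
    """Inner product g = k^T s of the spatial filter with the stimulus."""
    k = np.asarray(k, dtype=float)
    s = np.asarray(s, dtype=float)
    if k.shape != s.shape:
        raise ValueError("filter and stimulus lengths differ")
    return float(k @ s)


def fit_single_logistic(g: np.ndarray, y: np.ndarray):
    """Least-squares single logistic fit; returns (b, m, r, g0)."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = g.min(), g.max()
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate linear predictions (zero spread)")
    # slope sign from the correlation of y with g
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(g, y)[0, 1]
    if not np.isfinite(corr) or corr == 0:
        corr = 1.0
    r0 = 4.0 / span * np.sign(corr)
    x0 = [y.min(), y.max(), r0, 0.5 * (lo + hi)]
    bounds = (
        [0.0, 0.0, -np.inf, lo - 0.5 * span],
        [np.inf, np.inf, np.inf, hi + 0.5 * span],
    )
    res = least_squares(
        lambda th: logistic(g, *th) - y, x0, bounds=bounds, method="trf"
    )
    return res.x


def fit_bilogistic(g: np.ndarray, y: np.ndarray) -> BiLogistic:
    """Fit the bi-logistic nonlinearity to (linear prediction, count) pairs.

    A single logistic is fitted first; the bi-logistic is initialized so its
    dominant lobe (ON if the single-logistic slope is positive, else OFF)
    reproduces that curve, the other lobe starting flat.  Constraints:
    b >= 0, M_ON >= b, M_OFF >= b, r_ON >= 0, r_OFF >= 0.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.size < 20:
        raise ValueError("need at least 20 (g, y) pairs")
    b0, m0, r0, g00 = fit_single_logistic(g, y)
    lo, hi = g.min(), g.max()
    span = hi - lo
    eps = 1e-6
    b0 = max(b0, 0.0)
    m0 = max(m0, b0 + eps)
    # the secondary lobe starts small but alive (nonzero amplitude and
    # slope), otherwise its gradient vanishes and U-shapes cannot be found
    amp2 = b0 + 0.1 * (y.max() - y.min()) + eps
    r2 = 4.0 / span
    if r0 >= 0:  # dominant ON lobe
        x0 = [b0, m0, amp2, abs(r0), r2, g00, lo]
    else:  # dominant OFF lobe
        x0 = [b0, amp2, m0, r2, abs(r0), hi, g00]

    def resid(th):
        return BiLogistic(*th)(g) - y

    g_lo, g_hi = lo - 0.5 * span, hi + 0.5 * span
    lower = [0.0, 0.0, 0.0, 0.0, 0.0, g_lo, g_lo]
    upper = [np.inf] * 5 + [g_hi, g_hi]
    x0 = np.clip(x0, lower, upper)
    res = least_squares(resid, x0, bounds=(lower, upper), method="trf")
    th = res.x
    # enforce M >= b (the bounds only give M >= 0)
    if th[1] < th[0] or th[2] < th[0]:
        th = th.copy()
        th[1] = max(th[1], th[0])
        th[2] = max(th[2], th[0])
    return BiLogistic(*th)


def signal_power(counts: np.ndarray) -> float:
    """Signal power SP: the trial-noise-corrected across-image variance.

    SP = [Var(sum_n R_mn) - sum_n Var(R_mn)] / (N (N - 1)), variances taken
    across images (population convention, /M).  SP can come out slightly
    negative for unreliable cells; such cells are excluded upstream.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be (n_stimuli, n_trials) with N >= 2")
    n = counts.shape[1]
    var_sum = np.var(counts.sum(axis=1))
    sum_var = np.var(counts, axis=0).sum()
    return float((var_sum - sum_var) / (n * (n - 1)))


def cc_norm(y_hat: np.ndarray, counts: np.ndarray, sp: float | None = None) -> float:
    """Noise-normalized prediction correlation Cov(y, yhat)/sqrt(Var(yhat)*SP).

    Invariant to positively sloped affine rescaling of the prediction.
    Returns NaN when SP <= 0 (reliability too low for the measure).  ``sp``
    may be supplied externally (e.g. the cell-level estimate from the full
    image set, which is much better determined than a small-subset one);
    by default it is estimated from ``counts``.
    """
    counts = np.asarray(counts, dtype=float)
    y = counts.mean(axis=1)
    y_hat = np.asarray(y_hat, dtype=float)
    if sp is None:
        sp = signal_power(counts)
    if sp <= 0:
        return float("nan")
    cov = np.mean((y - y.mean()) * (y_hat - y_hat.mean()))
    var_hat = np.var(y_hat)
    if var_hat == 0:
        return float("nan")
    return float(cov / np.sqrt(var_hat * sp))


def crossvalidate_ln(
    table: TrialResponseTable,
    images: np.ndarray,
    rf: ParametricRF,
    n_folds: int = 10,
    seed: int = 0,
    pixel_size: float = PIXEL_SIZE_UM,
    quantized: bool = True,
) -> LNModelFit:
    """Fit and evaluate the LN model with 10-fold cross-validation.

    ``images`` is the stack of preprocessed contrast images, ordered to
    match the rows of ``table``.  Each fold's nonlinearity is fitted to the
    other 90% of images and scored by CCnorm on the held-out 10%; the
    reported performance is the mean over folds and the stored nonlinearity
    is the fold whose CCnorm is closest to that mean.
    """
    n_images = images.shape[0]
    if n_images != table.counts.shape[0]:
        raise ValueError("image stack and response table sizes differ")

    s0, k, origin = clip_to_rf(images[0], rf, pixel_size)
    side = int(np.sqrt(k.size))
    r0, c0 = origin
    crops = images[:, r0 : r0 + side, c0 : c0 + side].reshape(n_images, -1)
    g = crops @ k

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_images)
    folds = np.array_split(perm, n_folds)

    scores = []
    fits = []
    for test_idx in folds:
        train_mask = np.ones(n_images, dtype=bool)
        train_mask[test_idx] = False
        y_train = table.trial_mean()[train_mask]
        try:
            nl = fit_bilogistic(g[train_mask], y_train)
        except ValueError:
            warnings.warn("fold dropped: degenerate training data", stacklevel=2)
            continue
        y_hat = nl(g[test_idx])
        score = cc_norm(y_hat, table.counts[test_idx])
        if np.isnan(score):
            warnings.warn("fold dropped: undefined CCnorm", stacklevel=2)
            continue
        scores.append(score)
        fits.append(nl)

    if not scores:
        return LNModelFit(k, None, float("nan"), np.array([]), g)
    scores = np.asarray(scores)
    mean_score = float(scores.mean())
    best = fits[int(np.argmin(np.abs(scores - mean_score)))]
    return LNModelFit(k, best, mean_score, scores, g)
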