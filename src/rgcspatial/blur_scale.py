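"""Spatial-scale estimation from responses to blurred natural images.

Images are blurred with an isotropic 2-D Gaussian whose spatial scale is
defined as the diameter of its 2-sigma contour (scale = 4 sigma), matching
the RF-center diameter convention.  For each blur scale the symmetrized
R^2 between blurred-image and original-image spike counts measures how much
the response changed; the R^2 for zero blur is taken between odd- and
even-trial averages of the original responses.  A logistic fit of R^2
versus blur scale yields the cell's "natural spatial scale" (the fit
midpoint): the finer the spatial structure a cell is sensitive to, the
smaller the blur that disrupts its responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_data import symmetrized_r2
from .gratings import _fit_logistic_midpoint

__all__ = ["BlurCurve", "blur_image", "blur_r2_curve", "mean_response_difference"]

DEFAULT_SCALES_UM = (30.0, 60.0, 120.0, 240.0, 480.0, 960.0)


@dataclass
class BlurCurve:
    scales: np.ndarray  # um, starting at 0
    r2: np.ndarray
    natural_scale: float
    resolved: bool


def blur_image(image: np.ndarray, scale_um: float, pixel_um: float = 7.5) -> np.ndarray:
    """Gaussian blur at a given spatial scale (2-sigma diameter, um).

    scale 0 returns the input unchanged; reflective boundary handling keeps
    the mean pixel value away from borders.
    """
    if scale_um < 0:
        raise ValueError("blur scale must be nonnegative")
    if scale_um == 0:
        return image.copy()
    sigma_px = (scale_um / 4.0) / pixel_um
    return gaussian_filter(np.asarray(image, dtype=float), sigma_px, mode="reflect")


def blur_r2_curve(
    responses_by_scale: dict,
    original_counts: np.ndarray,
) -> BlurCurve:
    """Similarity-vs-blur curve and its logistic midpoint.

    ``responses_by_scale`` maps blur scale (um, > 0) to the trial-mean count
    vector for the blurred images; ``original_counts`` is the
    (n_images, n_trials) count matrix for the unblurred images.  The R^2 at
    scale 0 is the odd/even-trial R^2 of the original responses.
    """
    scales = sorted(responses_by_scale)
    if len(scales) < 3:
        raise ValueError("need at least 3 nonzero blur scales")
    counts = np.asarray(original_counts, dtype=float)
    idx = np.arange(1, counts.shape[1] + 1)
    r0 = symmetrized_r2(
        counts[:, idx % 2 == 0].mean(axis=1), counts[:, idx % 2 == 1].mean(axis=1)
    )
    orig_mean = counts.mean(axis=1)
    r2s = [r0] + [
        symmetrized_r2(np.asarray(responses_by_scale[s], float), orig_mean)
        for s in scales
    ]
    all_scales = np.array([0.0] + list(scales))
    r2s = np.asarray(r2s, dtype=float)
    # fit on R^2 clipped to [0, 1.05]: negative values mean "no similarity"
    # and the logistic asymptotes are constrained to the same range
    mid, ok = _fit_logistic_midpoint(all_scales, np.clip(r2s, 0.0, 1.05))
    return BlurCurve(all_scales, r2s, mid, ok)


def mean_response_difference(
    blurred_mean: np.ndarray, original_mean: np.ndarray
) -> float:
    """Mean over images of (blurred - original) count, in units of the max."""
    b = np.asarray(blurred_mean, dtype=float)
    o = np.asarray(original_mean, dtype=float)
    return float(np.mean(b - o) / o.max())
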