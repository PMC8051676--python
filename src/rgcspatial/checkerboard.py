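"""Checkerboard-flash contrast combinations and iso-response analysis.

The stimulus interleaves two sets of checkerboard tiles (A and B) flashed
at Weber contrasts (s_A, s_B) drawn from a polar design (24 equidistant
angles x 10 radii between 3% and 100% contrast, plus the (0, 0) blank).
The shape of the resulting response surface over the (s_A, s_B) plane
diagnoses how the cell combines the two local inputs, independently of any
output nonlinearity:

* rectification index RI — weighted ratio of opposing-contrast responses
  (s_A = c, s_B = -c) to single-component responses (s_A = c, s_B = 0):
  0 for linear integration (the opposing stimulus is a null stimulus),
  1 for full rectification of nonpreferred local contrast;
* convexity index CI = 1 - weighted ratio of homogeneous responses
  (s_A = s_B = c/2, the same linearly integrated contrast) to
  single-component responses: 0 for linear integration, > 0 for convex
  (outward-bulging) iso-response contours, < 0 for cells preferring
  spatially homogeneous stimulation;
* relative sensitivity (w_B - w_A)/(w_B + w_A) of the two tile sets,
  from the regression slopes w along the half-axes.

All responses are background-subtracted (the measured (0, 0) response for
the full-field stimulus; the interpolated origin for the local variant).
Responses at contrast pairs that were not sampled directly are estimated
by a C1 scattered-data interpolant over the sampled disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator
from skimage import measure

__all__ = [
    "ContrastPairSurface",
    "IsoIndices",
    "design_contrast_space",
    "interpolate_response",
    "half_axis_weights",
    "rectification_index",
    "convexity_index",
    "relative_sensitivity",
    "iso_response_contours",
    "select_local_patch",
]

HALF_AXES = ("+A", "-A", "+B", "-B")


def design_contrast_space(
    n_angles: int = 24,
    n_radii: int = 10,
    r_min: float = 0.03,
    r_max: float = 1.0,
) -> np.ndarray:
    """Polar grid of contrast pairs plus the (0, 0) blank, shape (N, 2)."""
    if n_angles < 4:
        raise ValueError("need at least 4 angles")
    if r_max > 1.0:
        raise ValueError("radial contrast cannot exceed 100%")
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    radii = np.linspace(r_min, r_max, n_radii)
    aa, rr = np.meshgrid(angles, radii)
    pts = np.stack([rr * np.cos(aa), rr * np.sin(aa)], axis=-1).reshape(-1, 2)
    return np.vstack([pts, [0.0, 0.0]])


@dataclass
class ContrastPairSurface:
    """Trial-averaged responses over the sampled (s_A, s_B) disk."""

    points: np.ndarray  # (N, 2) contrast pairs
    counts: np.ndarray  # (N,) mean spike counts
    background_from_origin_sample: bool = True
    _interp: CloughTocher2DInterpolator = field(default=None, repr=False)
    _nearest: NearestNDInterpolator = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        radii = np.hypot(self.points[:, 0], self.points[:, 1])
        if np.any(radii > 1.0 + 1e-9):
            raise ValueError("sampled radii must be <= 1 (100% contrast)")
        self._interp = CloughTocher2DInterpolator(self.points, self.counts)
        self._nearest = NearestNDInterpolator(self.points, self.counts)

    @property
    def background_count(self) -> float:
        """Response at (0, 0): measured sample if present, else interpolated."""
        at_origin = np.all(self.points == 0.0, axis=1)
        if self.background_from_origin_sample and at_origin.any():
            return float(self.counts[at_origin].mean())
        return float(self._nearest(0.0, 0.0))


def interpolate_response(surface: ContrastPairSurface, s_a, s_b) -> np.ndarray:
    """Estimate the mean count at (s_a, s_b) from nearby sampled pairs.

    Exact at sample points and continuous inside the convex hull of the
    design; queries outside the hull fall back to the nearest sample with
    a warning.
    """
    s_a = np.atleast_1d(np.asarray(s_a, dtype=float))
    s_b = np.atleast_1d(np.asarray(s_b, dtype=float))
    vals = surface._interp(s_a, s_b)
    bad = ~np.isfinite(vals)
    if bad.any():
        warnings.warn(
            "query outside sampled hull; nearest-sample fallback", stacklevel=2
        )
        vals[bad] = surface._nearest(s_a[bad], s_b[bad])
    return vals if vals.size > 1 else float(vals[0])


def _half_axis_samples(surface: ContrastPairSurface, axis: str):
    """(radii, background-subtracted responses) along one half-axis."""
    pts = surface.points
    tol = 1e-9
    if axis == "+A":
        mask = (pts[:, 0] > tol) & (np.abs(pts[:, 1]) <= tol)
        r = pts[mask, 0]
    elif axis == "-A":
        mask = (pts[:, 0] < -tol) & (np.abs(pts[:, 1]) <= tol)
        r = -pts[mask, 0]
    elif axis == "+B":
        mask = (pts[:, 1] > tol) & (np.abs(pts[:, 0]) <= tol)
        r = pts[mask, 1]
    elif axis == "-B":
        mask = (pts[:, 1] < -tol) & (np.abs(pts[:, 0]) <= tol)
        r = -pts[mask, 1]
    else:
        raise ValueError(f"unknown half-axis {axis!r}")
    resp = surface.counts[mask] - surface.background_count
    if r.size >= 3:
        return r, resp
    # half-axis not sampled directly: reconstruct by interpolation
    radii = np.linspace(0.1, 1.0, 10)
    sign = 1.0 if axis[0] == "+" else -1.0
    if axis[1] == "A":
        vals = interpolate_response(surface, sign * radii, np.zeros_like(radii))
    else:
        vals = interpolate_response(surface, np.zeros_like(radii), sign * radii)
    return radii, np.atleast_1d(vals) - surface.background_count


def half_axis_weights(surface: ContrastPairSurface) -> dict:
    """Sensitivity w_i per half-axis: OLS slope of response vs contrast."""
    out = {}
    for axis in HALF_AXES:
        r, resp = _half_axis_samples(surface, axis)
        out[axis] = float(stats.linregress(r, resp).slope)
    return out


def _index_responses(surface: ContrastPairSurface, c: float):
    """Background-subtracted r_half, r_oppos, r_same keyed by half-axis."""
    if np.hypot(c, c) > 1.0 + 1e-9:
        # the (c, -c) pair must lie inside the sampled unit disk
        raise ValueError("contrast level too high: (c, -c) outside the disk")
    bg = surface.background_count
    q = lambda a, b: interpolate_response(surface, a, b) - bg
    r_half = {"+A": q(c, 0), "-A": q(-c, 0), "+B": q(0, c), "-B": q(0, -c)}
    # two distinct opposing-contrast responses, each bordering two half-axes
    opp_ab = q(c, -c)  # borders +A and -B
    opp_ba = q(-c, c)  # borders -A and +B
    r_oppos = {"+A": opp_ab, "-B": opp_ab, "-A": opp_ba, "+B": opp_ba}
    # two distinct homogeneous responses at the same integrated contrast
    same_p = q(c / 2, c / 2)
    same_n = q(-c / 2, -c / 2)
    r_same = {"+A": same_p, "+B": same_p, "-A": same_n, "-B": same_n}
    return r_half, r_oppos, r_same


def rectification_index(surface: ContrastPairSurface, c: float = 0.6) -> float:
    """RI = sum_i w_i r_oppos,i / sum_i w_i r_half,i over the 4 half-axes."""
    w = half_axis_weights(surface)
    r_half, r_oppos, _ = _index_responses(surface, c)
    den = sum(w[a] * r_half[a] for a in HALF_AXES)
    if den <= 0:
        return float("nan")
    num = sum(w[a] * r_oppos[a] for a in HALF_AXES)
    return float(num / den)


def convexity_index(surface: ContrastPairSurface, c: float = 0.6) -> float:
    """CI = 1 - sum_i w_i r_same,i / sum_i w_i r_half,i."""
    w = half_axis_weights(surface)
    r_half, _, r_same = _index_responses(surface, c)
    den = sum(w[a] * r_half[a] for a in HALF_AXES)
    if den <= 0:
        return float("nan")
    num = sum(w[a] * r_same[a] for a in HALF_AXES)
    return float(1.0 - num / den)


def relative_sensitivity(surface: ContrastPairSurface) -> float:
    """(w_B - w_A)/(w_B + w_A) for the preferred-sign half-axis pair."""
    w = half_axis_weights(surface)
    pos = 0.5 * (w["+A"] + w["+B"])
    neg = 0.5 * (w["-A"] + w["-B"])
    wa, wb = (w["+A"], w["+B"]) if pos >= neg else (w["-A"], w["-B"])
    if wa + wb <= 0:
        return float("nan")
    return float((wb - wa) / (wb + wa))


def iso_response_contours(
    surface: ContrastPairSurface,
    levels=(0.3, 0.5, 0.7),
    grid_n: int = 201,
) -> dict:
    """Iso-response contour polylines at fractions of the maximum count.

    The background-subtracted surface is rasterized on a grid_n x grid_n
    grid over [-1, 1]^2 (nearest-sample fill outside the sampled hull) and
    level sets are extracted by marching squares.  Returns
    {level_fraction: [polyline (k, 2) arrays in contrast coordinates]}.
    """
    axis = np.linspace(-1.0, 1.0, grid_n)
    xx, yy = np.meshgrid(axis, axis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = interpolate_response(surface, xx.ravel(), yy.ravel())
    z = np.asarray(z).reshape(grid_n, grid_n) - surface.background_count
    # contours are only meaningful inside the sampled contrast disk;
    # marching squares treats NaN as masked and stops contours there
    r_max = np.hypot(surface.points[:, 0], surface.points[:, 1]).max()
    z[np.hypot(xx, yy) > r_max] = np.nan
    zmax = surface.counts.max() - surface.background_count
    out = {}
    for frac in levels:
        level = frac * zmax
        polys = []
        if level <= np.nanmax(z):
            for c in measure.find_contours(z, level):
                # rows are s_B (y), cols are s_A (x)
                sa = np.interp(c[:, 1], np.arange(grid_n), axis)
                sb = np.interp(c[:, 0], np.arange(grid_n), axis)
                polys.append(np.stack([sa, sb], axis=-1))
        out[frac] = polys
    return out


def select_local_patch(
    patch_centers: np.ndarray, rf, rf_radius: float | None = None
):
    """Nearest stimulus patch to the RF center; distance in RF radii.

    Returns (patch_index, normalized_distance).
    """
    from .rf_estimation import rf_center_diameter

    centers = np.atleast_2d(np.asarray(patch_centers, dtype=float))
    if centers.size == 0:
        raise ValueError("no patches")
    d = np.hypot(*(centers - rf.center_mean).T)
    i = int(np.argmin(d))
    if rf_radius is None:
        rf_radius = 0.5 * rf_center_diameter(rf)
    return i, float(d[i] / rf_radius)
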