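"""Functional cell-class detection: IRS, DS, OS, ON/OFF and OFF-OS clustering.

* Image-recurrence-sensitive (IRS) cells respond with a sharp transient
  when a shifted grating returns to its pre-transition position but not
  when it lands contrast-reversed.  The recurrence sensitivity index
  contrasts the maximal PSTH derivative (successive 10 ms bins, 50-200 ms
  after fixation onset) between recurrence and contrast-reversal
  transitions, averaged over the four fixation positions.
* Direction and orientation selectivity are the magnitudes of the
  normalized complex sums sum_theta r_theta e^{i theta} (DSI) and
  sum_theta r_theta e^{i 2 theta} (OSI) over eight grating directions;
  significance is assessed by shuffling responses over angles and trials.
* ON/OFF type comes from the sign of the first qualifying peak of the
  fitted temporal filter (peaks under 25% of the largest deflection are
  disregarded).
* OFF-OS cells split into linear and nonlinear groups by 2-means
  clustering on standardized LN performance, SC sensitivity, rectification
  and convexity features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema
from sklearn.cluster import KMeans

from .core_data import Psth

__all__ = [
    "TuningCurve",
    "recurrence_sensitivity_index",
    "direction_selectivity",
    "orientation_selectivity",
    "permutation_significance",
    "classify_tuning",
    "classify_on_off",
    "cluster_off_os",
]


@dataclass
class TuningCurve:
    angles: np.ndarray  # radians, 8 equidistant
    rates: np.ndarray  # mean rate per direction, Hz

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


def _max_derivative(psth: Psth, t0: float = 0.05, t1: float = 0.2) -> float:
    """Maximal successive-bin increase of the PSTH within [t0, t1]."""
    centers = 0.5 * (psth.bin_edges[:-1] + psth.bin_edges[1:])
    diffs = np.diff(psth.rate)
    # derivative attributed to the later bin of each successive pair
    mask = (centers[1:] >= t0) & (centers[1:] <= t1)
    if not mask.any():
        raise ValueError("analysis window not covered by PSTH")
    return float(diffs[mask].max())


def recurrence_sensitivity_index(
    psths: dict,
    reversed_partner: dict | None = None,
    rsi_threshold: float = 0.7,
    peak_rate_threshold: float = 50.0,
):
    """(RSI, mean recurrence peak rate, is_irs) from the 16 transition PSTHs.

    ``psths`` maps (start_position, target_position) in {0..3}^2 to a Psth.
    Positions two phases apart show the same grating contrast-reversed;
    by default partner(i) = (i + 2) mod 4.  For each target grating i,
    D_rec is the maximal PSTH derivative after a recurrence transition
    (i -> i) and D_change after a contrast-reversal transition
    (partner(i) -> i); RSI = mean_i (D_rec - D_change)/(D_rec + D_change).
    """
    if len(psths) != 16:
        raise ValueError("need all 16 transition PSTHs")
    if reversed_partner is None:
        reversed_partner = {i: (i + 2) % 4 for i in range(4)}
    terms = []
    peaks = []
    for i in range(4):
        d_rec = _max_derivative(psths[(i, i)])
        d_change = _max_derivative(psths[(reversed_partner[i], i)])
        denom = d_rec + d_change
        if denom == 0:
            return float("nan"), float("nan"), False
        terms.append((d_rec - d_change) / denom)
        peaks.append(psths[(i, i)].rate.max())
    rsi = float(np.mean(terms))
    peak = float(np.mean(peaks))
    return rsi, peak, bool(rsi > rsi_threshold and peak >= peak_rate_threshold)


def direction_selectivity(curve: TuningCurve):
    """(DSI, preferred direction): normalized complex sum over directions."""
    total = curve.rates.sum()
    if total <= 0:
        raise ValueError("all-zero tuning curve")
    z = np.sum(curve.rates * np.exp(1j * curve.angles)) / total
    return float(np.abs(z)), float(np.angle(z) % (2 * np.pi))


def orientation_selectivity(curve: TuningCurve):
    """(OSI, preferred orientation mod pi) from the doubled-angle sum.

    The preferred orientation is the line perpendicular to half the
    argument of the complex sum.
    """
    total = curve.rates.sum()
    if total <= 0:
        raise ValueError("all-zero tuning curve")
    z = np.sum(curve.rates * np.exp(2j * curve.angles)) / total
    pref = (0.5 * np.angle(z) + np.pi / 2.0) % np.pi
    return float(np.abs(z)), float(pref)


def permutation_significance(
    responses: np.ndarray,
    index_fn,
    angles: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Permutation p-value for a tuning index.

    ``responses`` is (n_angles, n_trials); the observed index is computed
    on per-angle trial means, and the null distribution by shuffling
    responses over all angles and trials.  Uses the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[1] < 2:
        raise ValueError("need (n_angles, n_trials) with >= 2 trials")
    angles = np.asarray(angles, dtype=float)
    observed = index_fn(TuningCurve(angles, responses.mean(axis=1)))[0]
    rng = np.random.default_rng(seed)
    flat = responses.ravel()
    n_ge = 0
    for _ in range(n_perm):
        shuf = rng.permutation(flat).reshape(responses.shape)
        val = index_fn(TuningCurve(angles, shuf.mean(axis=1)))[0]
        if val >= observed:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def permutation_significance_batch(
    responses: np.ndarray,
    angles: np.ndarray,
    harmonic: int = 1,
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Vectorized permutation p-value for DSI (harmonic=1) / OSI (harmonic=2).

    Same null and estimator as :func:`permutation_significance` but with
    all permutations evaluated as one matrix product, for calibration
    studies over many cells.
    """
    responses = np.asarray(responses, dtype=float)
    angles = np.asarray(angles, dtype=float)
    phase = np.exp(1j * harmonic * angles)
    means = responses.mean(axis=1)
    observed = np.abs(means @ phase) / means.sum()
    rng = np.random.default_rng(seed)
    flat = responses.ravel()
    idx = np.argsort(rng.random((n_perm, flat.size)), axis=1)
    shuf = flat[idx].reshape(n_perm, *responses.shape).mean(axis=2)
    null = np.abs(shuf @ phase) / shuf.sum(axis=1)
    return float((1 + np.sum(null >= observed)) / (1 + n_perm))


def classify_tuning(
    dsi: float,
    osi: float,
    p_ds: float,
    p_os: float,
    mean_rate_hz: float,
    is_irs: bool = False,
    index_threshold: float = 0.25,
    alpha: float = 0.01,
    min_rate_hz: float = 1.0,
) -> str:
    """DS/OS/other label from the tuning indices and permutation p-values.

    DS requires DSI > 0.25 significant at the 1% level; OS the analogous
    OSI criterion and that the cell is neither DS nor IRS; both require a
    mean rate above 1 Hz during the gratings.
    """
    if mean_rate_hz <= min_rate_hz:
        return "other"
    if dsi > index_threshold and p_ds < alpha:
        return "DS"
    if osi > index_threshold and p_os < alpha and not is_irs:
        return "OS"
    return "other"


def classify_on_off(kt_values: np.ndarray, lag_times: np.ndarray) -> str:
    """ON/OFF label from the sign of the first qualifying temporal peak.

    ``kt_values`` are samples of the fitted temporal filter on the lag grid
    (lag_times increasing, time before the spike).  Local extrema with
    unsigned amplitude below 25% of the largest deflection are disregarded;
    the sign of the remaining extremum closest to zero lag decides.
    """
    v = np.asarray(kt_values, dtype=float)
    order = np.argsort(lag_times)
    v = v[order]
    maxima = argrelextrema(v, np.greater_equal)[0]
    minima = argrelextrema(v, np.less_equal)[0]
    # include endpoints as candidate extrema
    cand = sorted(set(maxima) | set(minima) | {0, len(v) - 1})
    amp = np.abs(v).max()
    if amp == 0:
        return "unclassified"
    cand = [i for i in cand if np.abs(v[i]) >= 0.25 * amp]
    if not cand:
        return "unclassified"
    first = min(cand)
    return "ON" if v[first] > 0 else "OFF"


def cluster_off_os(
    features: np.ndarray,
    feature_mask: np.ndarray | None = None,
    n_restarts: int = 20,
    seed: int = 0,
):
    """Split cells into linear/nonlinear groups by 2-means clustering.

    ``features`` is (n_cells, 4) with columns (cc_norm, sc_slope, ri, ci);
    ``feature_mask`` marks available entries (missing checkerboard features
    allowed).  Complete-feature cells are clustered on standardized
    features; incomplete cells are assigned to the nearest centroid on
    their available standardized coordinates.  The group with the higher
    mean LN performance is labelled "linear".  Returns (labels, centroids).
    """
    x = np.asarray(features, dtype=float)
    if feature_mask is None:
        feature_mask = np.isfinite(x)
    complete = feature_mask.all(axis=1)
    if complete.sum() < 6:
        raise ValueError("need at least 6 complete-feature cells")
    xc = x[complete]
    mu = xc.mean(axis=0)
    sd = xc.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate features: zero variance")
    z = (xc - mu) / sd
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(z)
    # name by LN performance: cluster with higher mean cc_norm is "linear"
    cc = xc[:, 0]
    mean_cc = [cc[km.labels_ == k].mean() for k in (0, 1)]
    name = {int(np.argmax(mean_cc)): "linear", int(np.argmin(mean_cc)): "nonlinear"}
    labels = np.empty(x.shape[0], dtype=object)
    labels[complete] = [name[k] for k in km.labels_]
    for i in np.where(~complete)[0]:
        avail = feature_mask[i]
        zi = (x[i, avail] - mu[avail]) / sd[avail]
        d = np.linalg.norm(km.cluster_centers_[:, avail] - zi, axis=1)
        labels[i] = name[int(np.argmin(d))]
    return labels, km.cluster_centers_ * sd + mu
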