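"""Receptive-field estimation: spike-triggered average and parametric fit.

The RF is estimated from binary checkerboard white noise by reverse
correlation (STA over a 500 ms window) and summarized by a space-time
separable parametric model kS(x) * kT(t):

  kS(x) = N(x; mu, Sigma) - A_S * N(x; mu, kappa^2 Sigma)

with N an unnormalized (peak 1) 2-D Gaussian, A_S in [0, 1] the relative
surround strength and kappa >= 1 the surround extent scale, and

  kT(t) = p1 * ((t/tau1) * exp(-t/tau1 + 1))^n
        - p2 * ((t/tau2) * exp(-t/tau2 + 1))^n

a difference of two low-pass filters whose lobes peak at t = tau with value
p.  The RF-center diameter is that of the circle with the same area as the
2-sigma ellipse of the center Gaussian, d = 4 * det(Sigma)^(1/4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "Sta",
    "ParametricRF",
    "compute_sta",
    "eval_spatial_dog",
    "eval_temporal_filter",
    "fit_parametric_rf",
    "rf_center_diameter",
]


@dataclass
class Sta:
    """Spike-triggered average.

    ``values`` has shape (n_lags, ny, nx); lag index 0 is the frame nearest
    the spike and the lag axis spans 500 ms before the spike
    (n_lags = round(0.5 * frame_rate)).  Spatial coordinates are retinal
    micrometers with the origin at the stimulus-grid corner; the center of
    stixel (i, j) is at ((j + 0.5), (i + 0.5)) * stixel_size.
    """

    values: np.ndarray
    stixel_size: float  # um
    frame_rate: float  # Hz
    n_spikes: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("STA must be 3-D (lag, y, x)")

    @property
    def lag_times(self) -> np.ndarray:
        """Time before the spike of each lag (frame centers), seconds."""
        return (np.arange(self.values.shape[0]) + 0.5) / self.frame_rate

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape[1:]
        xs = (np.arange(nx) + 0.5) * self.stixel_size
        ys = (np.arange(ny) + 0.5) * self.stixel_size
        return np.meshgrid(xs, ys)


@dataclass
class ParametricRF:
    """Fitted space-time separable RF model."""

    center_mean: np.ndarray  # (2,), um
    center_cov: np.ndarray  # (2, 2), um^2, symmetric PD
    surround_strength: float  # A_S in [0, 1]
    surround_scale: float  # kappa >= 1
    p1: float = 1.0
    p2: float = 0.0
    tau1: float = 0.05
    tau2: float = 0.12
    n: float = 6.0
    fit_error: float = float("nan")

    def __post_init__(self) -> None:
        self.center_mean = np.asarray(self.center_mean, dtype=float)
        self.center_cov = np.asarray(self.center_cov, dtype=float)
        if not np.allclose(self.center_cov, self.center_cov.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.center_cov) <= 0):
            raise ValueError("Sigma must be positive definite")
        if not 0.0 <= self.surround_strength <= 1.0:
            raise ValueError("A_S must be in [0, 1]")
        if self.surround_scale < 1.0:
            raise ValueError("kappa must be >= 1")


def save_sta(path_prefix: str, sta: Sta) -> None:
    """Write an STA as an NPY array plus a JSON metadata sidecar."""
    import json

    np.save(path_prefix + ".npy", sta.values)
    meta = dict(
        stixel_size=sta.stixel_size,
        frame_rate=sta.frame_rate,
        n_spikes=sta.n_spikes,
    )
    with open(path_prefix + ".json", "w") as fh:
        json.dump(meta, fh)


def load_sta(path_prefix: str) -> Sta:
    import json

    values = np.load(path_prefix + ".npy")
    with open(path_prefix + ".json") as fh:
        meta = json.load(fh)
    return Sta(values, **meta)


def compute_sta(
    spikes: np.ndarray,
    stimulus_frames: np.ndarray,
    frame_times: np.ndarray,
    stixel_size: float,
    window: float = 0.5,
) -> Sta:
    """Reverse-correlation RF estimate from binary white noise.

    ``stimulus_frames`` is (n_frames, ny, nx) with contrast values in
    {-1, +1}; ``frame_times`` gives each frame's onset.  For each spike the
    preceding ``window`` seconds of frames are averaged, lag 0 being the
    frame on screen at the spike time.
    """
    spikes = np.asarray(spikes, dtype=float)
    frames = np.asarray(stimulus_frames, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    dt = float(np.median(np.diff(frame_times)))
    frame_rate = 1.0 / dt
    n_lags = int(round(window * frame_rate))

    if spikes.size < 100:
        warnings.warn("fewer than 100 spikes: STA will be noisy", stacklevel=2)

    # frame on screen at each spike
    idx = np.searchsorted(frame_times, spikes, side="right") - 1
    valid = idx >= n_lags - 1
    idx = idx[valid]
    sta = np.zeros((n_lags,) + frames.shape[1:])
    for lag in range(n_lags):
        sta[lag] = frames[idx - lag].mean(axis=0) if idx.size else 0.0
    return Sta(sta, stixel_size, frame_rate, n_spikes=int(idx.size))


def eval_spatial_dog(params: ParametricRF, x: np.ndarray) -> np.ndarray:
    """Difference-of-Gaussians spatial profile at locations ``x`` (um).

    ``x`` may be a single 2-vector or an (..., 2) array.  Both Gaussians are
    unnormalized (peak 1), so kS(mu) = 1 - A_S.
    """
    x = np.asarray(x, dtype=float)
    d = x - params.center_mean
    prec = np.linalg.inv(params.center_cov)
    q = np.einsum("...i,ij,...j->...", d, prec, d)
    center = np.exp(-0.5 * q)
    surround = np.exp(-0.5 * q / params.surround_scale**2)
    return center - params.surround_strength * surround


def eval_temporal_filter(params: ParametricRF, t: np.ndarray) -> np.ndarray:
    """Difference-of-low-pass temporal filter at times ``t`` > 0 before spike."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive (time before the spike)")

    def lobe(tau):
        return ((t / tau) * np.exp(-t / tau + 1.0)) ** params.n

    return params.p1 * lobe(params.tau1) - params.p2 * lobe(params.tau2)


def rf_center_diameter(params: ParametricRF) -> float:
    """Diameter (um) of the circle with the area of the 2-sigma ellipse.

    The 2-sigma ellipse has area 4*pi*sqrt(det Sigma); the equal-area circle
    has d = 4 * det(Sigma)^(1/4) — for isotropic Sigma = sigma^2 I this is
    4*sigma.
    """
    return float(4.0 * np.linalg.det(params.center_cov) ** 0.25)


def _spatial_model(theta_s, xx, yy):
    mx, my, sx, sy, rho, a_s, kappa = theta_s
    cov = np.array(
        [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
    )
    rf = ParametricRF(np.array([mx, my]), cov, a_s, kappa)
    pts = np.stack([xx, yy], axis=-1)
    return eval_spatial_dog(rf, pts)


def _temporal_model(theta_t, t):
    p1, p2, tau1, tau2, n = theta_t
    l1 = ((t / tau1) * np.exp(-t / tau1 + 1.0)) ** n
    l2 = ((t / tau2) * np.exp(-t / tau2 + 1.0)) ** n
    return p1 * l1 - p2 * l2


def fit_parametric_rf(
    sta: Sta,
    noise_floor_sd: float = 5.0,
    n_restarts: int = 3,
    seed: int = 0,
) -> ParametricRF:
    """Fit the separable parametric model to an STA by constrained MSE.

    Staged initialization: the spatial component is first fitted to the STA
    frame containing the largest-absolute element (sign-flipped if that
    element is negative, so the spatial center peak is positive), the
    temporal component to the time course of that element; the joint model
    is then refined with bound-constrained quasi-Newton optimization, with
    a few jittered restarts to guard against local minima.

    Raises ValueError when no element stands out from the noise floor
    (|peak| <= ``noise_floor_sd`` robust SDs of the STA entries).
    """
    v = sta.values
    robust_sd = 1.4826 * np.median(np.abs(v - np.median(v)))
    peak_idx = np.unravel_index(np.argmax(np.abs(v)), v.shape)
    peak = v[peak_idx]
    if robust_sd > 0 and abs(peak) <= noise_floor_sd * robust_sd:
        raise ValueError("no dominant STA element above the noise floor")

    lag0, iy, ix = peak_idx
    xx, yy = sta.pixel_centers()
    frame = v[lag0] * np.sign(peak)  # positive central peak convention
    tcourse = v[:, iy, ix]
    t = sta.lag_times
    px = sta.stixel_size

    # --- stage 1: spatial fit on the peak frame ---
    mx0 = (ix + 0.5) * px
    my0 = (iy + 0.5) * px
    # width init from the half-max region: its semi-axes are sqrt(2 ln 2)
    # sigma, and a 50% cut is robust to background noise
    mask = frame >= 0.5 * frame.max()
    c = np.sqrt(2.0 * np.log(2.0))
    if mask.sum() >= 3:
        sx0 = max(2.0 * np.std(xx[mask]) / c, 0.5 * px)
        sy0 = max(2.0 * np.std(yy[mask]) / c, 0.5 * px)
    else:
        w = np.clip(frame, 0, None)
        w = w / w.sum()
        sx0 = max(np.sqrt(np.sum(w * (xx - mx0) ** 2)), 0.5 * px)
        sy0 = max(np.sqrt(np.sum(w * (yy - my0) ** 2)), 0.5 * px)
    amp0 = frame.max()

    extent_x = xx.max() + 0.5 * px
    extent_y = yy.max() + 0.5 * px
    s_bounds = [
        (0.0, extent_x),
        (0.0, extent_y),
        (0.25 * px, extent_x),
        (0.25 * px, extent_y),
        (-0.95, 0.95),
        (0.0, 1.0),
        (1.0, 10.0),
    ]

    def s_loss(th):
        amp = th[7]
        return np.mean((amp * _spatial_model(th[:7], xx, yy) - frame) ** 2)

    opts = dict(maxiter=2000, ftol=1e-15, gtol=1e-12)
    th_s0 = np.array([mx0, my0, sx0, sy0, 0.0, 0.1, 2.0, amp0])
    res_s = minimize(
        s_loss, th_s0, method="L-BFGS-B", bounds=s_bounds + [(1e-9, None)],
        options=opts,
    )
    th_s = res_s.x

    # --- stage 2: temporal fit on the peak-pixel time course ---
    # The spatial peak is positive by convention, so the STA's sign lives in
    # kT: an OFF cell fits with its subtracted lobe (p2, tau2) peaking first.
    tc = tcourse
    sgn = np.sign(peak)
    t_early = max(t[np.argmax(tc * sgn)], t[0])
    late = tc * sgn
    late[t <= t_early] = np.inf
    t_late = t[np.argmin(late)] if np.isfinite(late).any() else 2 * t_early
    amp_early = max((tc * sgn).max(), 1e-3)
    amp_late = max(-(tc * sgn).min(), 0.0)
    if sgn >= 0:
        th_t0 = np.array([amp_early, amp_late, t_early, max(t_late, 1.2 * t_early), 6.0])
    else:
        th_t0 = np.array([amp_late, amp_early, max(t_late, 1.2 * t_early), t_early, 6.0])
    t_bounds = [(0.0, None), (0.0, None), (1e-3, 1.0), (1e-3, 1.0), (0.5, 20.0)]

    def t_loss(th):
        return np.mean((_temporal_model(th, t) - tc) ** 2)

    res_t = minimize(
        t_loss, th_t0, method="L-BFGS-B", bounds=t_bounds, options=opts
    )
    th_t = res_t.x

    # --- stage 3: joint refinement ---
    def j_loss(th):
        ks = _spatial_model(th[:7], xx, yy)
        kt = _temporal_model(th[7:], t)
        model = kt[:, None, None] * ks[None]
        return np.mean((model - v) ** 2)

    th0 = np.concatenate([th_s[:7], th_t])
    # fold the stage-1 amplitude into the temporal amplitudes
    th0[7] *= th_s[7]
    th0[8] *= th_s[7]
    bounds = s_bounds + t_bounds

    rng = np.random.default_rng(seed)
    best = None
    init_loss = j_loss(th0)
    for k in range(max(1, n_restarts)):
        start = th0 if k == 0 else th0 * rng.uniform(0.9, 1.1, size=th0.size)
        start = np.clip(
            start,
            [b[0] if b[0] is not None else -np.inf for b in bounds],
            [b[1] if b[1] is not None else np.inf for b in bounds],
        )
        res = minimize(
            j_loss, start, method="L-BFGS-B", bounds=bounds, options=opts
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun <= 1e-9 * np.mean(v**2):  # numerically exact already
            break
    th = best.x if best.fun <= init_loss else th0
    err = min(best.fun, init_loss)

    mx, my, sx, sy, rho, a_s, kappa = th[:7]
    cov = np.array([[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]])
    return ParametricRF(
        center_mean=np.array([mx, my]),
        center_cov=cov,
        surround_strength=float(np.clip(a_s, 0, 1)),
        surround_scale=float(max(kappa, 1.0)),
        p1=float(th[7]),
        p2=float(th[8]),
        tau1=float(th[9]),
        tau2=float(th[10]),
        n=float(th[11]),
        fit_error=float(err),
    )
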