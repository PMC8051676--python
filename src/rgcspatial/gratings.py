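"""Contrast-reversing grating analysis: spatial scale and the F2/F1 index.

Square-wave gratings of 100% contrast are reversed every second at several
bar widths and spatial phases.  Reversal-aligned PSTHs (10 ms bins,
excluding the first reversal after a gray period) yield two summaries per
cell: (i) the grating spatial scale, the midpoint of a logistic fit of
peak firing rate versus bar width, and (ii) the nonlinearity index
F2_max / F1_max, where F1 and F2 are the maximum Fourier amplitudes at the
reversal frequency and at twice that frequency, each maximized over all
bar widths and phases independently.  Frequency-doubled (F2) responses are
the classical signature of nonlinear spatial summation: a linear cell's
response to a reversing grating through a symmetric RF modulates at the
reversal frequency, while rectified subunits respond to every reversal.

In the flashed variant the two phases of a grating are flashed for 200 ms
each; the two response PSTHs are concatenated into one 400 ms trace that is
analyzed like a reversal period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_data import Psth, build_psth
from .ln_model import logistic

__all__ = [
    "GratingSchedule",
    "GratingResponseSet",
    "grating_psths",
    "grating_spatial_scale",
    "f1_f2_index",
    "fourier_amplitude",
]


@dataclass
class GratingSchedule:
    """Reversal schedule: arrays of event times, bar widths, phases, kinds.

    ``kind`` entries are 'reversal', 'flash_on' or 'gray'.  The first
    reversal after a gray period is excluded from averaging.
    """

    time: np.ndarray
    bar_width: np.ndarray
    phase: np.ndarray
    kind: np.ndarray
    period: float = 1.0  # reversal period, s


def read_schedule_csv(path, period: float = 2.0) -> "GratingSchedule":
    """Read a schedule CSV with columns time, bar_width, phase, event."""
    import pandas as pd

    df = pd.read_csv(path)
    return GratingSchedule(
        time=df["time"].to_numpy(float),
        bar_width=df["bar_width"].to_numpy(float),
        phase=df["phase"].to_numpy(int),
        kind=df["event"].to_numpy(str),
        period=period,
    )


@dataclass
class GratingResponseSet:
    entries: dict = field(default_factory=dict)  # (bar_width, phase) -> Psth
    period: float = 1.0
    contrast: float = 1.0


def grating_psths(
    spikes: np.ndarray, schedule: GratingSchedule, bin_width: float = 0.010
) -> GratingResponseSet:
    """Reversal-aligned PSTHs per (bar width, phase) entry."""
    out = GratingResponseSet(period=schedule.period)
    kinds = np.asarray(schedule.kind)
    after_gray = np.zeros(len(kinds), dtype=bool)
    prev_gray = True  # treat the very first event as post-gray
    for i, k in enumerate(kinds):
        if k == "gray":
            prev_gray = True
            continue
        after_gray[i] = prev_gray
        prev_gray = False

    keys = set(
        zip(np.asarray(schedule.bar_width), np.asarray(schedule.phase))
    )
    for w, ph in sorted(keys):
        mask = (
            (np.asarray(schedule.bar_width) == w)
            & (np.asarray(schedule.phase) == ph)
            & (kinds != "gray")
            & ~after_gray
        )
        onsets = np.asarray(schedule.time)[mask]
        if onsets.size == 0:
            continue
        out.entries[(float(w), int(ph))] = build_psth(
            spikes, onsets, schedule.period, bin_width
        )
    return out


def _fit_logistic_midpoint(
    x: np.ndarray, y: np.ndarray, mid_bounds: tuple | None = None
) -> tuple[float, bool]:
    """Logistic fit of y vs x; returns (midpoint, ok).

    ``ok`` is False when the logistic does not beat a constant fit
    (degenerate, e.g. flat profile) or the midpoint escapes its bounds
    (default: the sampled range widened by its own span on both sides).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span = x.max() - x.min()
    if mid_bounds is None:
        mid_bounds = (x.min() - span, x.max() + span)
    sgn = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0
    x0 = [max(y.min(), 0.0), y.max(), sgn * 4.0 / max(span, 1e-9), np.median(x)]
    lower = [0.0, 0.0, -np.inf, mid_bounds[0]]
    upper = [np.inf, np.inf, np.inf, mid_bounds[1]]
    res = least_squares(
        lambda th: logistic(x, *th) - y,
        np.clip(x0, lower, upper),
        bounds=(lower, upper),
    )
    sse_fit = float(np.sum(res.fun**2))
    sse_const = float(np.sum((y - y.mean()) ** 2))
    mid = float(res.x[3])
    eps = 1e-6 * max(span, 1.0)
    ok = sse_fit < 0.95 * sse_const and (
        mid_bounds[0] + eps < mid < mid_bounds[1] - eps
    )
    return mid, ok


def grating_spatial_scale(resp: GratingResponseSet):
    """Midpoint (um) of the logistic fit of peak PSTH rate vs bar width.

    Peak rate is taken across time bins and spatial phases for each bar
    width; homogeneous-illumination reversals (bar width >= 6 mm), when
    present, enter as the largest width and anchor the upper asymptote.
    The midpoint is constrained to [0, 2 x largest finite grating width]
    — a spatial scale is nonnegative, and beyond the sampled gratings the
    profile carries no information about it.  Returns (scale_um, ok);
    ok is False for non-sigmoidal profiles or a midpoint at its bounds.
    """
    widths = sorted({w for w, _ in resp.entries})
    if len(widths) < 4:
        raise ValueError("need at least 4 bar widths")
    peaks = [
        max(resp.entries[(w, ph)].rate.max() for ww, ph in resp.entries if ww == w)
        for w in widths
    ]
    finite = [w for w in widths if w < 6000.0]
    hi = 2.0 * max(finite) if finite else 2.0 * max(widths)
    # bar widths span decades, so the logistic is fitted on a log-width
    # axis; the midpoint is reported in um
    log_mid, ok = _fit_logistic_midpoint(
        np.log10(widths),
        np.asarray(peaks),
        mid_bounds=(np.log10(widths[0] / 2.0), np.log10(hi)),
    )
    return float(10.0**log_mid), ok


def fourier_amplitude(rate: np.ndarray, harmonic: int) -> float:
    """Amplitude 2|X_h|/n of the PSTH's h-th harmonic over one period."""
    n = len(rate)
    x = np.fft.rfft(rate)
    return float(2.0 * np.abs(x[harmonic]) / n)


def f1_f2_index(resp: GratingResponseSet):
    """(F1_max, F2_max, F2/F1) over all bar widths and phases.

    F1 and F2 are maximized over entries independently, capturing the
    largest luminance-driven and the largest spatial-contrast-driven
    modulation wherever each occurs.  Index undefined (NaN) if F1_max = 0.
    """
    if not resp.entries:
        raise ValueError("empty response set")
    f1s, f2s = [], []
    for psth in resp.entries.values():
        f1s.append(fourier_amplitude(psth.rate, 1))
        f2s.append(fourier_amplitude(psth.rate, 2))
    f1 = max(f1s)
    f2 = max(f2s)
    idx = f2 / f1 if f1 > 0 else float("nan")
    return f1, f2, idx


def flashed_grating_psth(psth_a: Psth, psth_b: Psth) -> Psth:
    """Concatenate the two 200 ms phase responses into one 400 ms trace."""
    if psth_a.bin_width != psth_b.bin_width:
        raise ValueError("bin widths differ")
    rate = np.concatenate([psth_a.rate, psth_b.rate])
    bw = psth_a.bin_width
    edges = np.arange(len(rate) + 1) * bw
    return Psth(edges, rate, min(psth_a.n_trials_averaged, psth_b.n_trials_averaged))
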