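"""Spike-train containers, trial-response extraction and reliability screening.

All analyses downstream start from the same primitives: spike times per
stimulus epoch, spike counts in a fixed window after each stimulus onset
(250 ms for flashed stimuli), PSTHs with 10 ms bins, and two reliability
statistics used to include or exclude cells — a symmetrized even/odd-trial
R^2 and a first-five/last-five trial drift correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "TrialResponseTable",
    "Psth",
    "count_spikes",
    "build_psth",
    "symmetrized_r2",
    "drift_correlation",
    "apply_inclusion_filters",
    "load_spike_csv",
    "save_spike_npz",
    "load_spike_npz",
    "save_response_table",
]


@dataclass
class SpikeTrainSet:
    """Per-cell spike times organized by stimulus epoch.

    ``epochs`` maps an epoch name (e.g. ``"image_flash"``) to a sorted array
    of spike times in seconds relative to epoch start.  ``trial_index`` maps
    an epoch name to a DataFrame with columns ``stimulus_id``, ``trial``,
    ``onset`` (seconds).
    """

    cell_id: str
    epochs: dict = field(default_factory=dict)
    trial_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spikes in self.epochs.items():
            arr = np.asarray(spikes, dtype=float)
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"spike times in epoch {name!r} not sorted")
            self.epochs[name] = arr
        for name, tab in self.trial_index.items():
            df = pd.DataFrame(tab)
            dup = df.duplicated(subset=["stimulus_id", "trial"])
            if dup.any():
                raise ValueError(f"duplicate (stimulus_id, trial) in {name!r}")
            self.trial_index[name] = df


@dataclass
class TrialResponseTable:
    """Spike counts per stimulus and trial in a fixed post-onset window."""

    stimulus_ids: list
    counts: np.ndarray  # (n_stimuli, n_trials)
    window: tuple  # (t0, t1) seconds relative to onset

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (n_stimuli, n_trials)")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def trial_mean(self) -> np.ndarray:
        return np.nanmean(self.counts, axis=1)

    def split_mean(self, which: str) -> np.ndarray:
        """Mean over odd or even trials; trials are numbered from 1."""
        idx = np.arange(1, self.n_trials + 1)
        mask = (idx % 2 == 1) if which == "odd" else (idx % 2 == 0)
        return np.nanmean(self.counts[:, mask], axis=1)


@dataclass
class Psth:
    """Peristimulus time histogram in spikes/s."""

    bin_edges: np.ndarray
    rate: np.ndarray
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.rate) != len(self.bin_edges) - 1:
            raise ValueError("rate length must be len(bin_edges) - 1")
        if np.any(self.rate < 0):
            raise ValueError("PSTH rates must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def count_spikes(
    spikes: Sequence[float],
    onsets: Sequence[float],
    window: tuple = (0.0, 0.25),
    stimulus_ids: Sequence | None = None,
) -> TrialResponseTable:
    """Count spikes in a half-open window [onset+t0, onset+t1) per trial.

    ``onsets`` is a flat list of trial onset times; ``stimulus_ids`` gives the
    stimulus shown on each onset (defaults to one stimulus per onset).  The
    returned table has one row per distinct stimulus and one column per trial
    of that stimulus.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("empty onset list")
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    if onsets.size > 1 and np.any(np.diff(onsets) < (t1 - t0)):
        warnings.warn("count windows overlap across onsets", stacklevel=2)

    spikes = np.asarray(spikes, dtype=float)
    # half-open window: searchsorted left at onset+t0, left at onset+t1
    lo = np.searchsorted(spikes, onsets + t0, side="left")
    hi = np.searchsorted(spikes, onsets + t1, side="left")
    per_onset = (hi - lo).astype(float)

    if stimulus_ids is None:
        stimulus_ids = np.zeros(onsets.size, dtype=int)
    stimulus_ids = np.asarray(stimulus_ids)
    uniq = pd.unique(stimulus_ids)
    n_trials = int(np.max(np.bincount(pd.factorize(stimulus_ids)[0])))
    counts = np.full((len(uniq), n_trials), np.nan)
    for i, sid in enumerate(uniq):
        vals = per_onset[stimulus_ids == sid]
        counts[i, : len(vals)] = vals
    return TrialResponseTable(list(uniq), counts, (t0, t1))


def build_psth(
    spikes: Sequence[float],
    onsets: Sequence[float],
    duration: float,
    bin_width: float = 0.010,
) -> Psth:
    """Trial-averaged PSTH in spikes/s with fixed-width bins."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("zero trials")
    n_bins = int(round(duration / bin_width))
    if abs(n_bins * bin_width - duration) > 1e-9:
        raise ValueError("duration must be a multiple of bin_width")
    spikes = np.asarray(spikes, dtype=float)
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for t in onsets:
        rel = spikes[(spikes >= t) & (spikes < t + duration)] - t
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (onsets.size * bin_width)
    return Psth(edges, rate, int(onsets.size))


def symmetrized_r2(even_means: np.ndarray, odd_means: np.ndarray) -> float:
    """Symmetrized coefficient of determination between trial-split means.

    R^2 = 1 - (1/2) * SS(e-o)/SS(o-mean_o) - (1/2) * SS(o-e)/SS(e-mean_e).
    Equals 1 iff the two halves are identical; NaN when either half has zero
    variance (such cells are excluded downstream).
    """
    e = np.asarray(even_means, dtype=float)
    o = np.asarray(odd_means, dtype=float)
    if e.shape != o.shape or e.size < 3:
        raise ValueError("inputs must be equal-length vectors with n >= 3")
    ss_o = np.sum((o - o.mean()) ** 2)
    ss_e = np.sum((e - e.mean()) ** 2)
    if ss_o == 0 or ss_e == 0:
        return float("nan")
    diff = np.sum((e - o) ** 2)
    return float(1.0 - 0.5 * diff / ss_o - 0.5 * diff / ss_e)


def drift_correlation(first5_means: np.ndarray, last5_means: np.ndarray) -> float:
    """Pearson r over stimuli between early-trial and late-trial mean responses.

    A global response scaling (rundown affecting all images proportionally)
    gives r = 1 and is not grounds for exclusion.  Constant vectors give NaN.
    """
    a = np.asarray(first5_means, dtype=float)
    b = np.asarray(last5_means, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length vectors with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def apply_inclusion_filters(
    table: TrialResponseTable,
    r2_threshold: float,
    drift_threshold: float | None = None,
) -> bool:
    """Reliability screen applied before every population analysis.

    True iff the even/odd symmetrized R^2 exceeds ``r2_threshold`` and, when
    ``drift_threshold`` is given, the first-five/last-five trial correlation
    exceeds it.  NaN statistics fail the screen.
    """
    if table.n_trials < 2:
        raise ValueError("need at least 2 trials")
    r2 = symmetrized_r2(table.split_mean("even"), table.split_mean("odd"))
    if not (r2 > r2_threshold):  # NaN fails
        return False
    if drift_threshold is not None:
        k = min(5, table.n_trials // 2)
        first = np.nanmean(table.counts[:, :k], axis=1)
        last = np.nanmean(table.counts[:, -k:], axis=1)
        r = drift_correlation(first, last)
        if not (r > drift_threshold):
            return False
    return True


def load_spike_csv(path) -> dict:
    """Read the plain-text spike container.

    Columns: cell_id, epoch, trial, stimulus_id, spike_time.  Returns a dict
    of cell_id -> SpikeTrainSet (trial_index left empty; onsets are carried
    by stimulus schedules, not the spike file).
    """
    df = pd.read_csv(path)
    out = {}
    for cid, sub in df.groupby("cell_id"):
        epochs = {
            ep: np.sort(grp["spike_time"].to_numpy(float))
            for ep, grp in sub.groupby("epoch")
        }
        out[cid] = SpikeTrainSet(str(cid), epochs=epochs)
    return out


def save_spike_npz(path, cells: dict) -> None:
    """Write cells (cell_id -> SpikeTrainSet) to an NPZ container.

    Arrays are keyed ``{cell_id}/{epoch}``; the trial index is not stored
    (onsets belong to stimulus schedules).
    """
    arrays = {}
    for cid, sts in cells.items():
        for epoch, spikes in sts.epochs.items():
            arrays[f"{cid}/{epoch}"] = np.asarray(spikes, dtype=float)
    np.savez(path, **arrays)


def load_spike_npz(path) -> dict:
    """Read the NPZ spike container written by :func:`save_spike_npz`."""
    out: dict = {}
    with np.load(path) as data:
        for key in data.files:
            cid, epoch = key.split("/", 1)
            out.setdefault(cid, {})[epoch] = data[key]
    return {cid: SpikeTrainSet(cid, epochs=eps) for cid, eps in out.items()}


def save_response_table(table: TrialResponseTable, path) -> None:
    df = pd.DataFrame(
        table.counts,
        index=pd.Index(table.stimulus_ids, name="stimulus_id"),
        columns=[f"trial_{j + 1}" for j in range(table.n_trials)],
    )
    df.to_csv(path)
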