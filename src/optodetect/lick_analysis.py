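"""Lick-related fluorescence modulation and spontaneous lick-bout detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["LickModulation", "smooth_licks", "lick_correlation", "detect_lick_bouts"]

TRIAL_EXCLUSION_S = (0.0, 4.0)  # post-stimulus period removed from spontaneous analyses


@dataclass
class LickModulation:
    r: np.ndarray  # per-neuron Pearson correlation
    p: np.ndarray
    modulated: np.ndarray  # boolean, p < threshold (NaN r -> False)
    sign: np.ndarray  # +1 / -1 / 0 (undefined)
    fraction_modulated: float


def smooth_licks(lick_times, timebase, sigma: float = 0.5) -> np.ndarray:
    """Continuous lick-rate trace: unit-mass Gaussians at each lick time."""
    timebase = np.asarray(timebase, dtype=float)
    lick_times = np.asarray(lick_times, dtype=float)
    trace = np.zeros(timebase.shape)
    for t in lick_times:
        trace += stats.norm.pdf(timebase, loc=t, scale=sigma)
    return trace


def _stim_mask(timebase, stim_onsets, window=TRIAL_EXCLUSION_S):
    """Boolean mask of samples inside any post-stimulus exclusion window."""
    mask = np.zeros(timebase.shape, dtype=bool)
    for onset in np.atleast_1d(np.asarray(stim_onsets, dtype=float)):
        mask |= (timebase >= onset + window[0]) & (timebase <= onset + window[1])
    return mask


def spontaneous_licks(lick_times, stim_onsets, window=TRIAL_EXCLUSION_S) -> np.ndarray:
    """Licks falling outside every post-stimulus exclusion window."""
    licks = np.asarray(lick_times, dtype=float)
    if licks.size == 0:
        return licks
    keep = ~_stim_mask(licks, stim_onsets, window)
    return licks[keep]


def lick_correlation(
    f_cell: np.ndarray,
    lick_times,
    volume_times: np.ndarray,
    stim_onsets,
    sigma: float = 0.5,
    exclusion_window=TRIAL_EXCLUSION_S,
    min_samples: int = 30,
    p_threshold: float = 0.05,
) -> LickModulation:
    """Per-neuron Pearson correlation with the smoothed lick trace.

    Samples inside photostimulation trial periods (0-4 s post onset) are
    removed, and the analysis spans the time between the first and last
    spontaneous lick.  Zero-variance neurons get NaN r/p and are not
    counted as modulated.
    """
    f_cell = np.atleast_2d(np.asarray(f_cell, dtype=float))
    volume_times = np.asarray(volume_times, dtype=float)
    spont = spontaneous_licks(lick_times, stim_onsets, exclusion_window)
    if spont.size == 0:
        raise ValueError("no spontaneous licks: correlation span undefined")

    keep = (
        (volume_times >= spont[0])
        & (volume_times <= spont[-1])
        & ~_stim_mask(volume_times, stim_onsets, exclusion_window)
    )
    if keep.sum() < min_samples:
        raise ValueError(f"only {int(keep.sum())} retained samples; need >= {min_samples}")

    lick_trace = smooth_licks(lick_times, volume_times, sigma=sigma)[keep]
    n_neurons = f_cell.shape[0]
    r = np.full(n_neurons, np.nan)
    p = np.full(n_neurons, np.nan)
    if np.ptp(lick_trace) > 0:
        for i in range(n_neurons):
            y = f_cell[i, keep]
            if np.ptp(y) == 0:
                continue
            r[i], p[i] = stats.pearsonr(lick_trace, y)
    modulated = np.where(np.isfinite(p), p < p_threshold, False)
    sign = np.where(np.isfinite(r), np.sign(r), 0.0)
    return LickModulation(
        r=r,
        p=p,
        modulated=modulated,
        sign=sign,
        fraction_modulated=float(modulated.mean()),
    )


def detect_lick_bouts(
    lick_times,
    min_licks: int = 3,
    within_bout_ili: float = 0.5,
    pre_quiet: float = 1.0,
    stim_onsets=None,
    exclusion_window=TRIAL_EXCLUSION_S,
) -> np.ndarray:
    """Onset times of spontaneous lick bouts.

    A bout is a maximal run of >= ``min_licks`` licks with consecutive
    inter-lick intervals <= ``within_bout_ili`` whose first lick follows
    any preceding lick by >= ``pre_quiet`` and falls outside every
    post-stimulus exclusion window.
    """
    licks = np.asarray(lick_times, dtype=float)
    if licks.size and np.any(np.diff(licks) < 0):
        raise ValueError("lick times must be sorted")
    if licks.size < min_licks:
        return np.empty(0)

    gaps = np.diff(licks)
    run_starts = np.concatenate([[0], np.flatnonzero(gaps > within_bout_ili) + 1])
    run_ends = np.concatenate([np.flatnonzero(gaps > within_bout_ili), [licks.size - 1]])

    onsets = []
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 < min_licks:
            continue
        if s > 0 and licks[s] - licks[s - 1] < pre_quiet:
            continue
        if stim_onsets is not None and _stim_mask(
            np.array([licks[s]]), stim_onsets, exclusion_window
        )[0]:
            continue
        onsets.append(licks[s])
    return np.asarray(onsets)
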