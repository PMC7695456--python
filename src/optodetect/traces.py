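"""ROI trace processing: neuropil subtraction, artefact masking, trial responses.

Neuropil contamination is removed as ``f_cell = f_roi - c * f_neuropil``
with ``c`` estimated per ROI by robust regression on masked, 10x
downsampled data and bounded to [0.5, 1]; ``f_cell`` is then re-baselined
so its 33rd percentile matches that of ``f_roi``.  Trial responses are
dF/sigmaF scalars: baseline-mean-subtracted, baseline-SD-normalised means
over a post-onset response window, computed only on volumes outside the
photostimulation artefact-exclusion epoch (5 consecutive volumes per
trial: the volume containing the onset, the one before it, and the three
after).
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm

__all__ = [
    "estimate_neuropil_coefficient",
    "session_neuropil_coefficients",
    "subtract_and_rebaseline",
    "artefact_exclusion_mask",
    "extract_trial_responses",
    "NEUROPIL_BOUNDS",
    "N_EXCLUDED_VOLUMES",
]

NEUROPIL_BOUNDS = (0.5, 1.0)
#: volumes excluded per trial: 1 containing onset + 1 before + 3 after
N_EXCLUDED_VOLUMES = 5
_MIN_REGRESSION_POINTS = 20


def estimate_neuropil_coefficient(
    f_roi: np.ndarray,
    f_neuropil: np.ndarray,
    stim_exclusion_mask: np.ndarray | None = None,
    downsample: int = 10,
    min_points: int = _MIN_REGRESSION_POINTS,
) -> float:
    """Robust-regression slope of f_roi on f_neuropil, clipped to [0.5, 1].

    ``stim_exclusion_mask`` is a boolean array marking volumes to drop
    (photostimulation epochs) before downsampling.  Returns NaN as a
    sentinel when the estimate is unreliable (too few points, a constant
    regressor, non-convergence or a non-finite slope); callers substitute
    the session median via :func:`session_neuropil_coefficients`.
    """
    f_roi = np.asarray(f_roi, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_roi.shape != f_neuropil.shape:
        raise ValueError("f_roi and f_neuropil must have the same length")
    keep = np.ones(f_roi.shape, dtype=bool) if stim_exclusion_mask is None else ~np.asarray(
        stim_exclusion_mask, dtype=bool
    )
    y = f_roi[keep][::downsample]
    x = f_neuropil[keep][::downsample]
    if y.size < min_points or np.ptp(x) == 0:
        return np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight())
            slope = float(model.fit().params[1])
    except Exception:
        return np.nan
    if not np.isfinite(slope):
        return np.nan
    return float(min(max(slope, NEUROPIL_BOUNDS[0]), NEUROPIL_BOUNDS[1]))


def session_neuropil_coefficients(
    f_roi: np.ndarray, f_neuropil: np.ndarray, stim_exclusion_mask: np.ndarray | None = None, **kw
) -> np.ndarray:
    """Per-neuron coefficients with session-median substitution for sentinels."""
    c = np.array(
        [
            estimate_neuropil_coefficient(r, n, stim_exclusion_mask, **kw)
            for r, n in zip(np.atleast_2d(f_roi), np.atleast_2d(f_neuropil))
        ]
    )
    bad = ~np.isfinite(c)
    if bad.all():
        raise ValueError("no neuropil coefficient could be reliably estimated")
    if bad.any():
        c[bad] = np.median(c[~bad])
    return c


def subtract_and_rebaseline(f_roi: np.ndarray, f_neuropil: np.ndarray, c: float) -> np.ndarray:
    """f_cell = f_roi - c * f_neuropil, shifted so P33(f_cell) = P33(f_roi)."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_cell = f_roi - c * np.asarray(f_neuropil, dtype=float)
    return f_cell - np.percentile(f_cell, 33) + np.percentile(f_roi, 33)


def _volume_of(onset: float, volume_times: np.ndarray) -> int:
    """Index of the volume whose acquisition interval contains ``onset``."""
    dt = float(np.median(np.diff(volume_times)))
    if onset < volume_times[0] or onset >= volume_times[-1] + dt:
        raise ValueError(f"trial onset {onset} s falls outside the recorded span")
    return int(np.searchsorted(volume_times, onset, side="right") - 1)


def artefact_exclusion_mask(trial_onsets, volume_times) -> np.ndarray:
    """Per-trial indices of the 5 excluded peri-stimulus volumes.

    Returns an (n_trials, 5) integer array: for each onset, the volume
    containing it, the volume immediately before, and the three after —
    the same count on every trial so trial types stay comparable.
    """
    volume_times = np.asarray(volume_times, dtype=float)
    if np.any(np.diff(volume_times) <= 0):
        raise ValueError("volume_times must be strictly increasing")
    onsets = np.atleast_1d(np.asarray(trial_onsets, dtype=float))
    mask = np.empty((onsets.size, N_EXCLUDED_VOLUMES), dtype=int)
    for i, onset in enumerate(onsets):
        k = _volume_of(onset, volume_times)
        if k - 1 < 0 or k + 3 >= volume_times.size:
            raise ValueError(
                f"trial onset {onset} s too close to recording edge for artefact exclusion"
            )
        mask[i] = np.arange(k - 1, k + 4)
    return mask


def extract_trial_responses(
    f_cell: np.ndarray,
    volume_times: np.ndarray,
    trial_onsets,
    mask: np.ndarray | None = None,
    baseline_s: float = 1.0,
    response_window_s: tuple[float, float] = (0.7, 1.0),
) -> np.ndarray:
    """dF/sigmaF response scalars, neurons x trials.

    Per neuron and trial: mean f_cell over unmasked volumes whose midpoint
    lies in ``response_window_s`` post onset, minus the mean over unmasked
    volumes in the ``baseline_s`` pre-onset period, divided by the
    baseline SD.  A zero baseline SD yields NaN (propagated, never zero).
    """
    f_cell = np.atleast_2d(np.asarray(f_cell, dtype=float))
    volume_times = np.asarray(volume_times, dtype=float)
    onsets = np.atleast_1d(np.asarray(trial_onsets, dtype=float))
    if mask is None:
        mask = artefact_exclusion_mask(onsets, volume_times)

    dt = float(np.median(np.diff(volume_times)))
    mid = volume_times + dt / 2.0
    n_neurons = f_cell.shape[0]
    responses = np.full((n_neurons, onsets.size), np.nan)
    for j, onset in enumerate(onsets):
        excluded = np.zeros(volume_times.size, dtype=bool)
        excluded[mask[j]] = True
        base_idx = np.flatnonzero((mid >= onset - baseline_s) & (mid < onset) & ~excluded)
        resp_idx = np.flatnonzero(
            (mid - onset >= response_window_s[0]) & (mid - onset <= response_window_s[1]) & ~excluded
        )
        if base_idx.size < 2 or resp_idx.size == 0:
            raise ValueError(f"trial {j}: insufficient unmasked baseline/response volumes")
        base = f_cell[:, base_idx]
        mu, sd = base.mean(axis=1), base.std(axis=1, ddof=1)
        ok = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            responses[ok, j] = (f_cell[ok][:, resp_idx].mean(axis=1) - mu[ok]) / sd[ok]
    return responses
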