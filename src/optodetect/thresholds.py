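"""Per-neuron activation/suppression thresholds calibrated to a fixed FP rate.

Thresholds are built from each neuron's response distribution on correct
reject (CR) catch trials:

    thr_activation  = mean_catch + sd_catch * sf_activation
    thr_suppression = mean_catch - sd_catch * sf_suppression

where the session-wide scaling factors ``sf_*`` are found by sweeping
candidate values (1-3 in steps of 0.1), estimating for each candidate the
median held-out proportion of neurons crossing threshold over permuted
80:20 train:test splits of the CR catch trials, cubic-interpolating that
curve and inverting it at the target false-positive rate (5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize

__all__ = [
    "ThresholdSet",
    "CalibrationCurve",
    "compute_thresholds",
    "median_fp_curve",
    "calibrate_scaling_factor",
    "classify_responses",
    "ACTIVATED",
    "SUPPRESSED",
    "NONE",
]

ACTIVATED: int = 1
SUPPRESSED: int = -1
NONE: int = 0

DEFAULT_SWEEP = np.round(np.arange(1.0, 3.0 + 1e-9, 0.1), 10)


@dataclass
class ThresholdSet:
    mean_catch: np.ndarray
    sd_catch: np.ndarray
    sf_activation: float
    sf_suppression: float
    thr_activation: np.ndarray = field(init=False)
    thr_suppression: np.ndarray = field(init=False)

    def __post_init__(self):
        self.thr_activation = self.mean_catch + self.sd_catch * self.sf_activation
        self.thr_suppression = self.mean_catch - self.sd_catch * self.sf_suppression


@dataclass
class CalibrationCurve:
    """Median held-out FP proportion per sweep value plus the inverted factor."""

    sweep: np.ndarray
    median_fp: np.ndarray
    target_fp: float
    scaling_factor: float
    kind: str


def compute_thresholds(
    cr_catch_responses: np.ndarray, sf_act: float, sf_sup: float
) -> ThresholdSet:
    """Per-neuron thresholds from the full CR-catch response distribution.

    ``cr_catch_responses`` is neurons x CR trials.
    """
    resp = np.asarray(cr_catch_responses, dtype=float)
    if resp.ndim != 2 or resp.shape[1] < 2:
        raise ValueError("need a neurons x trials matrix with >= 2 CR catch trials")
    return ThresholdSet(
        mean_catch=resp.mean(axis=1),
        sd_catch=resp.std(axis=1, ddof=1),
        sf_activation=float(sf_act),
        sf_suppression=float(sf_sup),
    )


def _signed_z(resp_test, mu, sd, sign):
    # z such that crossing threshold at scaling factor s  <=>  z > s
    with np.errstate(divide="ignore", invalid="ignore"):
        z = sign * (resp_test - mu[:, None]) / sd[:, None]
    z[~np.isfinite(z)] = -np.inf  # zero-SD neurons can never cross
    return z


def median_fp_curve(
    cr_catch_responses: np.ndarray,
    kind: str,
    sweep=DEFAULT_SWEEP,
    n_perm: int = 10_000,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> np.ndarray:
    """Median (over permuted train:test splits) held-out FP proportion per sweep value.

    On each permutation, per-neuron mean/SD come from the training CR
    trials; the fraction of neurons crossing threshold is computed on each
    test trial and averaged over test trials.  The same permuted splits
    are shared across sweep values (the per-split crossing fraction is a
    monotone function of the scaling factor, so the sweep reduces to
    counting exceedances of one z-score array per split).
    """
    resp = np.asarray(cr_catch_responses, dtype=float)
    if kind not in ("activation", "suppression"):
        raise ValueError(f"kind must be 'activation' or 'suppression', got {kind!r}")
    sign = 1.0 if kind == "activation" else -1.0
    sweep = np.asarray(sweep, dtype=float)
    n_neurons, n_trials = resp.shape
    n_test = max(1, int(round((1.0 - train_frac) * n_trials)))
    if n_trials - n_test < 2:
        raise ValueError("not enough CR catch trials for an 80:20 split with >= 2 training trials")

    rng = np.random.default_rng(seed)
    fp = np.empty((n_perm, sweep.size))
    for i in range(n_perm):
        perm = rng.permutation(n_trials)
        test, train = perm[:n_test], perm[n_test:]
        mu = resp[:, train].mean(axis=1)
        sd = resp[:, train].std(axis=1, ddof=1)
        z = np.sort(_signed_z(resp[:, test], mu, sd, sign), axis=None)
        # mean over test trials of per-trial neuron fraction == overall fraction
        fp[i] = 1.0 - np.searchsorted(z, sweep, side="right") / z.size
    return np.median(fp, axis=0)


def _invert_curve(sweep, median_fp, target_fp, kind):
    """Invert the (non-increasing) median-FP curve at target_fp."""
    lo, hi = float(sweep[0]), float(sweep[-1])
    if target_fp >= median_fp[0]:
        warnings.warn(
            f"target FP {target_fp} at or above curve maximum {median_fp[0]:.4g}; "
            f"returning sweep lower bound for {kind}",
            stacklevel=3,
        )
        return lo
    if target_fp <= median_fp[-1]:
        warnings.warn(
            f"target FP {target_fp} at or below curve minimum {median_fp[-1]:.4g}; "
            f"returning sweep upper bound for {kind}",
            stacklevel=3,
        )
        return hi

    spline = interpolate.CubicSpline(sweep, median_fp)
    dense = np.linspace(lo, hi, 2001)
    if np.any(np.diff(spline(dense)) > 1e-12):  # non-monotone cubic: use shape-preserving fit
        spline = interpolate.PchipInterpolator(sweep, median_fp)
    sf = optimize.brentq(lambda s: float(spline(s)) - target_fp, lo, hi)
    return float(min(max(sf, lo), hi))


def calibrate_scaling_factor(
    cr_catch_responses: np.ndarray,
    kind: str,
    sweep=DEFAULT_SWEEP,
    n_perm: int = 10_000,
    train_frac: float = 0.8,
    target_fp: float = 0.05,
    seed: int | None = None,
    return_curve: bool = False,
):
    """Scaling factor yielding the target held-out FP rate for one response kind."""
    sweep = np.asarray(sweep, dtype=float)
    median_fp = median_fp_curve(
        cr_catch_responses, kind, sweep=sweep, n_perm=n_perm, train_frac=train_frac, seed=seed
    )
    if np.any(np.diff(median_fp) > 1e-12):
        raise AssertionError("median FP curve must be non-increasing in the scaling factor")
    sf = _invert_curve(sweep, median_fp, target_fp, kind)
    if return_curve:
        return sf, CalibrationCurve(
            sweep=sweep, median_fp=median_fp, target_fp=target_fp, scaling_factor=sf, kind=kind
        )
    return sf


def classify_responses(responses: np.ndarray, thresholds: ThresholdSet):
    """Trinary classification of a neurons x trials response matrix.

    Strictly above the activation threshold -> ``ACTIVATED`` (1); strictly
    below the suppression threshold -> ``SUPPRESSED`` (-1); otherwise (and
    for non-finite responses, which are flagged) -> ``NONE`` (0).

    Returns ``(classes, undefined)`` where ``undefined`` marks entries
    with non-finite responses.
    """
    resp = np.asarray(responses, dtype=float)
    if resp.ndim != 2 or resp.shape[0] != thresholds.mean_catch.shape[0]:
        raise ValueError(
            f"responses shape {resp.shape} does not match {thresholds.mean_catch.shape[0]} neurons"
        )
    undefined = ~np.isfinite(resp)
    classes = np.zeros(resp.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        classes[resp > thresholds.thr_activation[:, None]] = ACTIVATED
        classes[resp < thresholds.thr_suppression[:, None]] = SUPPRESSED
    classes[undefined] = NONE
    return classes, undefined
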