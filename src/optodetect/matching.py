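"""Hit:miss matching — balance lick and no-lick trials before averaging metrics.

Licking itself drives network activity, and easy stimuli produce more
licks than hard ones, so per-trial-type metric averages are computed over
resampled trial sets with an enforced 50:50 hit:miss ratio: every
permutation takes all minority-response trials plus an equally sized
without-replacement sample of majority-response trials, and metrics are
averaged over the selected trials then over permutations.  Trial types
with only one response class are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchedMetrics", "match_hit_miss"]


@dataclass
class MatchedMetrics:
    """Permutation-averaged metrics for one trial type."""

    means: np.ndarray  # one value per metric column
    n_minority: int
    n_perm: int
    excluded: bool
    reason: str | None = None
    per_perm_means: np.ndarray | None = None  # n_perm x n_metrics
    selections: list[np.ndarray] | None = None  # trial indices per permutation


def match_hit_miss(
    licked: np.ndarray,
    per_trial_metrics: np.ndarray,
    n_perm: int = 100,
    seed: int | None = None,
    keep_permutations: bool = False,
) -> MatchedMetrics:
    """Hit:miss-matched metric means for the trials of a single trial type.

    Parameters
    ----------
    licked : boolean array, n_trials
        Response class per trial (hit/lick = True, miss/no-lick = False).
    per_trial_metrics : array, n_trials or n_trials x n_metrics
        Metric value(s) per trial, averaged over each permutation's
        selected trials.
    seed : int, optional
        Master seed; each permutation derives its own sub-seed so adding
        metrics or permutations never changes earlier samples.
    """
    licked = np.asarray(licked, dtype=bool)
    metrics = np.asarray(per_trial_metrics, dtype=float)
    if metrics.ndim == 1:
        metrics = metrics[:, None]
    if metrics.shape[0] != licked.size:
        raise ValueError("per_trial_metrics must have one row per trial")

    hit_idx = np.flatnonzero(licked)
    miss_idx = np.flatnonzero(~licked)
    if hit_idx.size == 0 or miss_idx.size == 0:
        return MatchedMetrics(
            means=np.full(metrics.shape[1], np.nan),
            n_minority=0,
            n_perm=n_perm,
            excluded=True,
            reason="single_response_class",
        )

    minority, majority = (hit_idx, miss_idx) if hit_idx.size <= miss_idx.size else (miss_idx, hit_idx)
    n_min = minority.size

    per_perm = np.empty((n_perm, metrics.shape[1]))
    selections = [] if keep_permutations else None
    for p in range(n_perm):
        rng = np.random.default_rng(None if seed is None else [seed, p])
        sampled = rng.choice(majority, size=n_min, replace=False)
        sel = np.concatenate([minority, sampled])
        per_perm[p] = metrics[sel].mean(axis=0)
        if selections is not None:
            selections.append(sel)

    return MatchedMetrics(
        means=per_perm.mean(axis=0),
        n_minority=n_min,
        n_perm=n_perm,
        excluded=False,
        per_perm_means=per_perm if keep_permutations else None,
        selections=selections,
    )
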