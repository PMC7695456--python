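"""Trial scoring, session exclusions and behavioural summary metrics.

Trial types are integers: the number of photostimulation target zones for
go trials, and ``CATCH`` (0) for catch trials.  Scoring uses a response
window of 0.15-1.15 s post stimulus onset; a first lick at or before
0.15 s excludes the trial as an unrealistically fast reaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "CATCH",
    "TrialRecord",
    "RTStats",
    "score_trials",
    "apply_session_exclusions",
    "response_rate",
    "catch_subtracted_rate",
    "d_prime",
    "reaction_time_stats",
    "behavior_summary",
]

#: Trial-type code for catch (no-stimulus) trials.
CATCH: int = 0

DEFAULT_RESPONSE_WINDOW = (0.15, 1.15)


@dataclass
class TrialRecord:
    """One go or catch trial with its licks and (after scoring) its outcome."""

    trial_index: int
    trial_type: int
    onset_s: float
    lick_times_s: np.ndarray
    autoreward_s: float | None = None  # seconds post onset, if auto-rewarded
    outcome: str | None = None
    reaction_time_s: float | None = None
    exclusion_reason: str | None = None

    @property
    def is_catch(self) -> bool:
        return self.trial_type == CATCH

    @property
    def excluded(self) -> bool:
        return self.outcome == "excluded"

    @property
    def licked(self) -> bool:
        return self.outcome in ("hit", "false_alarm")


@dataclass
class RTStats:
    mean: float
    sd: float
    n: int
    defined: bool


def _first_post_onset_lick(trial: TrialRecord) -> float | None:
    licks = np.asarray(trial.lick_times_s, dtype=float)
    if licks.size and (np.any(np.diff(licks) < 0) or np.any(licks < 0)):
        raise ValueError(f"trial {trial.trial_index}: lick times must be sorted and non-negative")
    rel = licks - trial.onset_s
    post = rel[rel > 0]
    return float(post[0]) if post.size else None


def score_trials(
    trials: list[TrialRecord],
    response_window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
) -> list[TrialRecord]:
    """Assign outcomes and reaction times from the first post-onset lick.

    Go trials: a first lick inside the response window is a hit (reaction
    time = lick latency), otherwise a miss.  Catch trials score false
    alarm / correct reject the same way.  Any trial whose first post-onset
    lick is at or before the window start is excluded (``rt_too_fast``).
    Auto-rewarded go trials are hits only if the lick lands before
    ``autoreward_s + 0.15`` s; later responses (or none) are misses.
    """
    lo, hi = response_window
    out = []
    for t in trials:
        first = _first_post_onset_lick(t)
        rec = replace(t, outcome=None, reaction_time_s=None, exclusion_reason=None)
        if first is not None and first <= lo:
            rec.outcome = "excluded"
            rec.exclusion_reason = "rt_too_fast"
        elif t.is_catch:
            if first is not None and lo < first <= hi:
                rec.outcome, rec.reaction_time_s = "false_alarm", first
            else:
                rec.outcome = "correct_reject"
        elif t.autoreward_s is not None:
            cutoff = t.autoreward_s + 0.15
            if first is not None and lo < first < cutoff:
                rec.outcome, rec.reaction_time_s = "hit", first
            else:
                rec.outcome = "miss"
        else:
            if first is not None and lo < first <= hi:
                rec.outcome, rec.reaction_time_s = "hit", first
            else:
                rec.outcome = "miss"
        out.append(rec)
    return out


def _sated_truncation_index(
    trials: list[TrialRecord], window: int, threshold: float
) -> int | None:
    """Index of the first latter-half easiest-type trial whose centred
    sliding window of easiest-type hit rates drops below ``threshold``."""
    go_types = [t.trial_type for t in trials if not t.is_catch]
    if not go_types:
        return None
    easiest = max(go_types)
    easy = [t for t in trials if t.trial_type == easiest and not t.excluded]
    if len(easy) < window:
        warnings.warn(
            f"fewer than {window} easiest-type trials; sated truncation rule skipped",
            stacklevel=2,
        )
        return None
    responses = np.array([1.0 if t.outcome == "hit" else 0.0 for t in easy])
    half = len(trials) / 2.0
    lo_off = window // 2  # centred window: w//2 before, w - w//2 - 1 after
    for i, t in enumerate(easy):
        if t.trial_index <= half:
            continue
        start, stop = i - lo_off, i - lo_off + window
        if start < 0 or stop > len(easy):
            continue
        if responses[start:stop].mean() < threshold:
            return t.trial_index
    return None


def apply_session_exclusions(
    trials: list[TrialRecord],
    recording_span: tuple[float, float] | None = None,
    pre_required_s: float = 2.0,
    post_required_s: float = 5.0,
    sated_window: int = 10,
    sated_threshold: float = 0.7,
) -> list[TrialRecord]:
    """Flag sated-animal truncation and recording-edge truncation.

    In the latter half of the session, the first easiest-type trial whose
    centred ``sated_window``-trial easiest-type hit rate falls below
    ``sated_threshold`` marks the sated point; that trial and everything
    after it are excluded.  If ``recording_span`` is given, trials whose
    analysis windows would be truncated by the recording edges are
    excluded too.
    """
    out = [replace(t) for t in trials]
    cut = _sated_truncation_index(out, sated_window, sated_threshold)
    for t in out:
        if cut is not None and t.trial_index >= cut and not t.excluded:
            t.outcome, t.exclusion_reason = "excluded", "sated"
        if recording_span is not None and not t.excluded:
            t0, t1 = recording_span
            if t.onset_s - pre_required_s < t0 or t.onset_s + post_required_s > t1:
                t.outcome, t.exclusion_reason = "excluded", "window_truncated"
                t.reaction_time_s = None
    return out


def _eligible(trials: list[TrialRecord], trial_type: int) -> list[TrialRecord]:
    return [t for t in trials if t.trial_type == trial_type and not t.excluded and t.outcome]


def response_rate(trials: list[TrialRecord], trial_type: int) -> float:
    """P(response) = n_lick / (n_lick + n_nolick) over eligible trials of a type."""
    elig = _eligible(trials, trial_type)
    if not elig:
        raise ValueError(f"no eligible scored trials of type {trial_type}")
    return sum(t.licked for t in elig) / len(elig)


def catch_subtracted_rate(trials: list[TrialRecord], trial_type: int) -> float:
    return response_rate(trials, trial_type) - response_rate(trials, CATCH)


def d_prime(hit_rate: float, fa_rate: float, n_go: int, n_catch: int) -> float:
    """Phi^-1(hit rate) - Phi^-1(false alarm rate) with boundary correction.

    Rates of 0 and 1 are replaced by 1/(2N) and 1 - 1/(2N) respectively,
    with N the trial count behind the rate.
    """
    if n_go <= 0 or n_catch <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must be in [0, 1]")

    def correct(rate, n):
        return min(max(rate, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))

    return float(stats.norm.ppf(correct(hit_rate, n_go)) - stats.norm.ppf(correct(fa_rate, n_catch)))


def reaction_time_stats(trials: list[TrialRecord], trial_type: int) -> RTStats:
    """Mean and sample SD of reaction times; undefined with <= 2 responses."""
    rts = [
        t.reaction_time_s
        for t in _eligible(trials, trial_type)
        if t.reaction_time_s is not None
    ]
    if len(rts) <= 2:
        return RTStats(mean=np.nan, sd=np.nan, n=len(rts), defined=False)
    arr = np.asarray(rts)
    return RTStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(rts), defined=True)


def behavior_summary(trials: list[TrialRecord]):
    """Per-trial-type summary table (P(response), catch-subtracted, RT, d')."""
    import pandas as pd

    types = sorted({t.trial_type for t in trials})
    have_catch = CATCH in types and bool(_eligible(trials, CATCH))
    p_catch = response_rate(trials, CATCH) if have_catch else np.nan
    n_catch = len(_eligible(trials, CATCH)) if have_catch else 0

    rows = []
    for tt in types:
        elig = _eligible(trials, tt)
        if not elig:
            continue
        p = response_rate(trials, tt)
        rt = reaction_time_stats(trials, tt)
        row = {
            "trial_type": tt,
            "n_trials": len(elig),
            "p_response": p,
            "p_response_catch_subtracted": p - p_catch if tt != CATCH else np.nan,
            "rt_mean_s": rt.mean,
            "rt_sd_s": rt.sd,
            "d_prime": (
                d_prime(p, p_catch, len(elig), n_catch)
                if tt != CATCH and have_catch
                else np.nan
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
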