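"""Seeded synthetic sessions with the statistical structure the pipeline assumes.

Generates a full session bundle — pseudorandom trial sequence (exact type
ratios, run-length limit, easy warm-up block), licking behaviour drawn
from a ground-truth log-normal psychometric curve, and calcium-like ROI /
neuropil traces with planted target activations, ensemble-size-scaled
background suppression and lick-coupled neurons — together with a
:class:`GroundTruth` record of the hidden parameters so every downstream
stage can be checked by parameter recovery.

Each sub-generator (sequence, behaviour, traces) runs on its own RNG
stream spawned from the master seed, so e.g. adding neurons never
perturbs the trial sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .behavior import CATCH, TrialRecord
from .psychometrics import psychometric

__all__ = [
    "PsychTruth",
    "SimConfig",
    "GroundTruth",
    "Session",
    "generate_trial_sequence",
    "plant_target_activations",
    "generate_behavior",
    "generate_traces",
    "simulate_session",
]


@dataclass(frozen=True)
class PsychTruth:
    """True psychometric parameters used by the behaviour generator."""

    m: float
    w: float
    lam: float
    gamma: float

    def validate(self):
        if self.w <= 0:
            raise ValueError("psych_truth.w must be positive")
        if self.lam < 0 or self.gamma < 0 or self.lam + self.gamma >= 1:
            raise ValueError("require 0 <= lam, gamma and lam + gamma < 1")


@dataclass
class SimConfig:
    # geometry / imaging
    n_neurons: int = 300
    fov_size_um: float = 500.0
    n_planes: int = 4
    plane_spacing_um: float = 33.0
    volume_rate_hz: float = 6.69
    # trial structure (trial_type_set[i] = target-zone count; CATCH = 0)
    trial_type_set: tuple[int, ...] = (CATCH, 5, 10, 25, 50, 75, 100, 200)
    trial_ratios: tuple[float, ...] = (0.15, 7 / 60, 7 / 60, 7 / 60, 7 / 60, 7 / 60, 7 / 60, 0.15)
    n_trials: int = 120
    warmup_trials: int = 10
    max_run_length: int = 3
    iti_mean_s: float = 10.0
    iti_jitter_s: float = 3.0
    # behaviour
    psych_truth: PsychTruth = field(default_factory=lambda: PsychTruth(np.log(21.0), 1.35, 0.05, 0.1))
    rt_median_s: float = 0.56
    rt_sigma: float = 0.25
    response_window: tuple[float, float] = (0.15, 1.15)
    bout_ili_s: tuple[float, float] = (0.08, 0.15)
    bout_duration_s: tuple[float, float] = (0.5, 1.5)
    spont_bout_rate_hz: float = 0.0
    # neural ground truth
    p_target_activation: float = 0.5
    suppression_base: float = 0.03
    suppression_slope: float = 2e-3  # added P(suppressed) per activated target
    spont_event_rate_hz: float = 0.01
    frac_lick_modulated: float = 0.2
    transient_amplitude_sd_units: float = 5.0
    suppression_amplitude_sd_units: float = -1.5
    lick_amplitude_sd_units: float = 3.0
    transient_tau_s: float = 1.0
    # trace model
    neuropil_coeff_true: float = 0.7
    baseline_offset: float = 100.0
    noise_sd: float = 10.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 300.0
    seed: int = 0

    def validate(self):
        ratios = np.asarray(self.trial_ratios, dtype=float)
        if len(ratios) != len(self.trial_type_set):
            raise ValueError("trial_ratios must match trial_type_set in length")
        if abs(ratios.sum() - 1.0) > 1e-9:
            raise ValueError(f"trial_ratios must sum to 1, got {ratios.sum()}")
        if np.any(ratios < 0):
            raise ValueError("trial_ratios must be non-negative")
        for name in ("p_target_activation", "suppression_base", "frac_lick_modulated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_planes < 1 or self.volume_rate_hz <= 0:
            raise ValueError("require n_planes >= 1 and volume_rate_hz > 0")
        if not 0.5 <= self.neuropil_coeff_true <= 1.0:
            raise ValueError("neuropil_coeff_true must lie in [0.5, 1]")
        self.psych_truth.validate()

    @property
    def go_types(self) -> list[int]:
        return [t for t in self.trial_type_set if t != CATCH]

    @property
    def easiest_type(self) -> int:
        return max(self.go_types)


@dataclass
class GroundTruth:
    """Hidden simulator parameters for parameter-recovery tests."""

    psych_truth: PsychTruth
    zone_coords_um: np.ndarray  # zones of the largest ensemble; type k uses the first k
    target_neuron_of_zone: np.ndarray  # neuron index per zone
    per_trial_activated_zones: list[np.ndarray]  # zone indices activated on each trial
    n_activated: np.ndarray  # per-trial activated-target count
    lick_coupling: np.ndarray  # signed per-neuron coefficient (0 = uncoupled)
    per_trial_suppressed: list[np.ndarray] | None = None  # neuron indices dipped per trial
    suppression_slope: float = 0.0
    suppression_base: float = 0.0
    neuropil_coeff_true: float = 0.7

    def target_mask(self, trial_type: int, n_neurons: int) -> np.ndarray:
        mask = np.zeros(n_neurons, dtype=bool)
        if trial_type != CATCH:
            mask[self.target_neuron_of_zone[:trial_type]] = True
        return mask


@dataclass
class Session:
    config: SimConfig
    trials: list[TrialRecord]
    f_roi: np.ndarray
    f_neuropil: np.ndarray
    centroids_um: np.ndarray
    volume_times_s: np.ndarray
    ground_truth: GroundTruth


def _streams(seed: int):
    seq, beh, trc = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(seq),
        np.random.default_rng(beh),
        np.random.default_rng(trc),
    )


def _largest_remainder_counts(ratios: np.ndarray, n: int) -> np.ndarray:
    exact = ratios * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _constrained_shuffle(counts: dict[int, int], max_run: int, context: tuple[int, int], rng):
    """Sequentially place trial types with run length <= max_run; restart on dead ends."""
    total = sum(counts.values())
    if total and max(counts.values()) > max_run * (total - max(counts.values()) + 1):
        dominant = max(counts, key=counts.get)
        raise ValueError(
            f"cannot satisfy run-length <= {max_run}: trial type {dominant} has "
            f"{counts[dominant]} of {total} trials"
        )
    for _ in range(1000):
        remaining = dict(counts)
        last, run = context
        seq = []
        ok = True
        for _ in range(total):
            types = [t for t, c in remaining.items() if c > 0 and (t != last or run < max_run)]
            if not types:
                ok = False
                break
            weights = np.array([remaining[t] for t in types], dtype=float)
            t = types[rng.choice(len(types), p=weights / weights.sum())]
            seq.append(t)
            remaining[t] -= 1
            run = run + 1 if t == last else 1
            last = t
        if ok:
            return seq
    raise ValueError(f"could not place trials under run-length <= {max_run} after 1000 restarts")


def generate_trial_sequence(config: SimConfig, seed: int | None = None):
    """Ordered (trial_type, onset_s) stubs honouring ratios and run-length limit.

    Type counts are exact (largest-remainder rounding of the ratios).  The
    sequence starts with ``warmup_trials`` easiest-type trials (taken out
    of that type's count); the remainder is pseudorandomly interleaved
    with at most ``max_run_length`` consecutive trials of any type, the
    warm-up block counting as context so no run extends across the
    boundary.  Inter-trial onset gaps are uniform in mean +/- jitter.
    """
    config.validate()
    if config.n_trials < 20:
        raise ValueError("n_trials must be >= 20")
    rng = _streams(config.seed)[0] if seed is None else np.random.default_rng(seed)

    ratios = np.asarray(config.trial_ratios, dtype=float)
    counts = _largest_remainder_counts(ratios, config.n_trials)
    by_type = dict(zip(config.trial_type_set, counts))

    warmup = []
    if config.warmup_trials > 0:
        easy = config.easiest_type
        if by_type.get(easy, 0) < config.warmup_trials:
            raise ValueError(
                f"easiest type {easy} has only {by_type.get(easy, 0)} trials; "
                f"cannot form a {config.warmup_trials}-trial warm-up block"
            )
        by_type[easy] -= config.warmup_trials
        warmup = [easy] * config.warmup_trials
        context = (easy, config.max_run_length)  # forbid extending the warm-up run
    else:
        context = (None, 0)

    types = warmup + _constrained_shuffle(
        {t: c for t, c in by_type.items() if c > 0}, config.max_run_length, context, rng
    )

    itis = rng.uniform(
        config.iti_mean_s - config.iti_jitter_s,
        config.iti_mean_s + config.iti_jitter_s,
        size=len(types),
    )
    onsets = np.cumsum(itis)
    return list(zip(types, onsets))


def plant_target_activations(sequence, config: SimConfig, rng) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-trial Bernoulli draws of which target zones activate."""
    activated, n_act = [], []
    for trial_type, _ in sequence:
        if trial_type == CATCH:
            zones = np.empty(0, dtype=int)
        else:
            hit = rng.random(trial_type) < config.p_target_activation
            zones = np.flatnonzero(hit)
        activated.append(zones)
        n_act.append(zones.size)
    return activated, np.asarray(n_act)


def _lick_bout(start: float, config: SimConfig, rng) -> np.ndarray:
    duration = rng.uniform(*config.bout_duration_s)
    times = [start]
    while times[-1] - start < duration:
        times.append(times[-1] + rng.uniform(*config.bout_ili_s))
    return np.asarray(times)


def generate_behavior(
    sequence,
    psych_truth: PsychTruth,
    seed=None,
    x_true: np.ndarray | None = None,
    config: SimConfig | None = None,
) -> list[TrialRecord]:
    """Trial records with lick times drawn from the ground-truth curve.

    Each go trial licks with probability psi(x_true) where ``x_true`` is
    the planted number of activated targets (nominal zone count if not
    given); catch trials (and x_true = 0) lick at the guess rate.  On lick
    trials the first lick latency is log-normal (median/sigma from the
    config) clipped to the response window, followed by a lick bout.
    """
    psych_truth.validate()
    config = config or SimConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = config.response_window

    records = []
    for i, (trial_type, onset) in enumerate(sequence):
        x = float(x_true[i]) if x_true is not None else float(trial_type)
        p_lick = psych_truth.gamma if x <= 0 else float(
            psychometric(x, psych_truth.m, psych_truth.w, psych_truth.lam, psych_truth.gamma)
        )
        licks = np.empty(0)
        if rng.random() < p_lick:
            rt = float(
                np.clip(
                    rng.lognormal(mean=np.log(config.rt_median_s), sigma=config.rt_sigma),
                    lo + 0.01,
                    hi - 0.05,
                )
            )
            licks = onset + _lick_bout(rt, config, rng)
        records.append(
            TrialRecord(
                trial_index=i,
                trial_type=trial_type,
                onset_s=onset,
                lick_times_s=licks,
            )
        )

    if config.spont_bout_rate_hz > 0:
        span = sequence[-1][1] + 5.0
        onsets = np.asarray([o for _, o in sequence])
        t = rng.uniform(2.0, span - 2.0, size=rng.poisson(config.spont_bout_rate_hz * span))
        for start in np.sort(t):
            if np.any((start - onsets >= -1.0) & (start - onsets <= 5.0)):
                continue  # keep spontaneous bouts clear of trial periods
            bout = _lick_bout(start, config, rng)
            rec = min(records, key=lambda r: abs(r.onset_s - start))
            rec.lick_times_s = np.sort(np.concatenate([rec.lick_times_s, bout]))
    return records


def _add_event(trace, volume_times, t0, amplitude, tau):
    i0 = np.searchsorted(volume_times, t0)
    i1 = min(len(volume_times), i0 + int(np.ceil(8 * tau * (len(volume_times) / (volume_times[-1] - volume_times[0])))) + 1)
    if i0 >= len(volume_times):
        return
    trace[i0:i1] += amplitude * np.exp(-(volume_times[i0:i1] - t0) / tau)


def _place_rois(config: SimConfig, n_zones: int, rng):
    """Zone coordinates plus ROI centroids: one neuron per zone, background clear of zones."""
    fov = config.fov_size_um
    z_max = config.n_planes * config.plane_spacing_um
    zones = np.empty((n_zones, 3))
    placed = 0
    while placed < n_zones:
        cand = rng.uniform(0, fov, size=2)
        if placed == 0 or np.min(np.linalg.norm(zones[:placed, :2] - cand, axis=1)) > 25.0:
            zones[placed] = (*cand, rng.uniform(0, z_max))
            placed += 1
    centroids = np.empty((config.n_neurons, 3))
    jitter = rng.uniform(-3, 3, size=(n_zones, 2))
    centroids[:n_zones, :2] = zones[:, :2] + jitter
    centroids[:n_zones, 2] = zones[:, 2]
    placed = n_zones
    while placed < config.n_neurons:
        cand = rng.uniform(0, fov, size=2)
        if np.min(np.linalg.norm(zones[:, :2] - cand, axis=1)) > 12.0:
            centroids[placed] = (*cand, rng.uniform(0, z_max))
            placed += 1
    return zones, centroids


def generate_traces(
    trial_records: list[TrialRecord],
    ground_truth: GroundTruth,
    config: SimConfig,
    rng,
):
    """Raw ROI + neuropil traces with planted transients.

    Neuropil = baseline + optional slow drift + smoothed noise shared
    across neurons; each ROI trace adds ``neuropil_coeff_true`` times the
    neuropil, private Gaussian noise, and exponential-kernel transients:
    positive for activated targets, negative dips for suppressed
    background neurons (probability ``suppression_base +
    suppression_slope * n_activated``), signed lick-coupled transients at
    lick-bout onsets.
    """
    n = config.n_neurons
    t_end = trial_records[-1].onset_s + 8.0
    dt = 1.0 / config.volume_rate_hz
    volume_times = np.arange(0.0, t_end, dt)
    nv = volume_times.size

    slow = np.convolve(rng.normal(0, 1, nv), np.ones(30) / 30, mode="same")
    drift = config.drift_amplitude * np.sin(2 * np.pi * volume_times / config.drift_period_s)
    f_neuropil_shared = config.baseline_offset + drift + config.noise_sd * slow
    f_neuropil = np.tile(f_neuropil_shared, (n, 1)) + rng.normal(0, 0.1 * config.noise_sd, (n, nv))

    f_roi = (
        config.neuropil_coeff_true * f_neuropil
        + config.baseline_offset
        + rng.normal(0, config.noise_sd, (n, nv))
    )

    amp = config.transient_amplitude_sd_units * config.noise_sd
    sup_amp = config.suppression_amplitude_sd_units * config.noise_sd
    lick_amp = config.lick_amplitude_sd_units * config.noise_sd
    tau = config.transient_tau_s

    target_of_zone = ground_truth.target_neuron_of_zone

    per_trial_suppressed = []
    for rec, zones in zip(trial_records, ground_truth.per_trial_activated_zones):
        n_act = zones.size
        for z in zones:
            _add_event(f_roi[target_of_zone[z]], volume_times, rec.onset_s, amp, tau)
        suppressed = np.empty(0, dtype=int)
        if rec.trial_type != CATCH:
            # background for this trial = everything outside this type's zones
            # (neurons of unused zones are ordinary background neurons here).
            # suppression_base/slope are on the network-proportion scale
            # (suppressed background count over ALL neurons); rescale to a
            # per-background-neuron Bernoulli probability.
            is_target = np.zeros(n, dtype=bool)
            is_target[target_of_zone[: rec.trial_type]] = True
            bg_scale = n / max(1, n - rec.trial_type)
            p_sup = min(
                1.0,
                bg_scale * (config.suppression_base + config.suppression_slope * n_act),
            )
            suppressed = np.flatnonzero((rng.random(n) < p_sup) & ~is_target)
            for i in suppressed:
                _add_event(f_roi[i], volume_times, rec.onset_s, sup_amp, tau)
        per_trial_suppressed.append(suppressed)
    ground_truth.per_trial_suppressed = per_trial_suppressed

    # spontaneous transients keep baseline activation rates nonzero
    if config.spont_event_rate_hz > 0:
        for i in range(n):
            k = rng.poisson(config.spont_event_rate_hz * t_end)
            for t0 in rng.uniform(0, t_end, size=k):
                _add_event(f_roi[i], volume_times, t0, amp, tau)

    # lick-coupled transients at bout onsets (first lick of each trial + spontaneous bouts)
    coupled = np.flatnonzero(ground_truth.lick_coupling != 0)
    if coupled.size:
        bout_onsets = [rec.lick_times_s[0] for rec in trial_records if rec.lick_times_s.size]
        for i in coupled:
            for t0 in bout_onsets:
                _add_event(
                    f_roi[i], volume_times, t0, ground_truth.lick_coupling[i] * lick_amp, tau
                )

    return f_roi, f_neuropil, volume_times


def simulate_session(config: SimConfig) -> Session:
    """Generate a complete seeded session bundle with ground truth."""
    config.validate()
    rng_seq, rng_beh, rng_trc = _streams(config.seed)

    sequence = generate_trial_sequence(config, seed=rng_seq)
    activated, n_act = plant_target_activations(sequence, config, rng_beh)
    trials = generate_behavior(
        sequence, config.psych_truth, seed=rng_beh, x_true=n_act, config=config
    )

    n_zones = config.easiest_type
    if config.n_neurons <= n_zones:
        raise ValueError(
            f"n_neurons={config.n_neurons} must exceed the largest ensemble size {n_zones}"
        )
    zones, centroids = _place_rois(config, n_zones, rng_trc)

    coupling = np.zeros(config.n_neurons)
    n_coupled = int(round(config.frac_lick_modulated * config.n_neurons))
    if n_coupled:
        idx = rng_trc.choice(config.n_neurons, size=n_coupled, replace=False)
        coupling[idx] = rng_trc.choice([-1.0, 1.0], size=n_coupled)

    truth = GroundTruth(
        psych_truth=config.psych_truth,
        zone_coords_um=zones,
        target_neuron_of_zone=np.arange(n_zones),
        per_trial_activated_zones=activated,
        n_activated=n_act,
        lick_coupling=coupling,
        suppression_slope=config.suppression_slope,
        suppression_base=config.suppression_base,
        neuropil_coeff_true=config.neuropil_coeff_true,
    )

    f_roi, f_neuropil, volume_times = generate_traces(trials, truth, config, rng_trc)
    return Session(
        config=config,
        trials=trials,
        f_roi=f_roi,
        f_neuropil=f_neuropil,
        centroids_um=centroids,
        volume_times_s=volume_times,
        ground_truth=truth,
    )
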