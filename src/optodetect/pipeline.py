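"""End-to-end composition: simulated/loaded session -> matched network metrics.

Glue over the stage modules for the common full-pipeline flow: score
behaviour, extract dF/sigmaF responses, calibrate thresholds on correct
reject catch trials, classify, and emit hit:miss-matched per-trial-type
network datapoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behavior, matching, targets, thresholds, traces

__all__ = ["TypePoint", "session_response_matrix", "matched_network_points"]


@dataclass
class TypePoint:
    """One hit:miss-matched datapoint (one trial type of one session)."""

    trial_type: int
    n_targets_activated: float
    p_activated_bg: float
    p_suppressed_bg: float
    p_lick: float
    n_trials: int
    n_minority: int


def session_response_matrix(session, scored=None):
    """Scored trials plus the neurons x trials dF/sigmaF response matrix."""
    if scored is None:
        scored = behavior.score_trials(session.trials)
    onsets = np.array([t.onset_s for t in session.trials])
    mask = traces.artefact_exclusion_mask(onsets, session.volume_times_s)
    responses = traces.extract_trial_responses(
        session.f_roi, session.volume_times_s, onsets, mask
    )
    return scored, responses


def matched_network_points(
    session,
    n_perm_calibration: int = 1000,
    n_perm_matching: int = 100,
    seed: int | None = None,
) -> list[TypePoint]:
    """Per-trial-type matched network metrics for one simulated session.

    Thresholds are calibrated on correct-reject catch trials; target
    labels come from the session's target-zone geometry; metrics are
    averaged under enforced 50:50 hit:miss resampling.  Trial types with
    a single response class are dropped.
    """
    scored, responses = session_response_matrix(session)
    cr = [i for i, t in enumerate(scored) if t.outcome == "correct_reject"]
    cr_resp = responses[:, cr]
    sf_act = thresholds.calibrate_scaling_factor(
        cr_resp, "activation", n_perm=n_perm_calibration, seed=seed
    )
    sf_sup = thresholds.calibrate_scaling_factor(
        cr_resp, "suppression", n_perm=n_perm_calibration, seed=seed
    )
    ts = thresholds.compute_thresholds(cr_resp, sf_act, sf_sup)
    classes, _ = thresholds.classify_responses(responses, ts)

    n_neurons = responses.shape[0]
    points = []
    for tt in session.config.go_types:
        idx = [i for i, t in enumerate(scored) if t.trial_type == tt and not t.excluded]
        if len(idx) < 2:
            continue
        zone_mask = targets.classify_rois(
            session.centroids_um, session.ground_truth.zone_coords_um[:tt]
        )
        counts = targets.per_trial_network_counts(classes[:, idx], zone_mask)
        metric = np.column_stack(
            [
                counts["act_targets"],
                counts["act_bg"] / n_neurons,
                counts["sup_bg"] / n_neurons,
            ]
        )
        licked = np.array([scored[i].licked for i in idx])
        m = matching.match_hit_miss(licked, metric, n_perm=n_perm_matching, seed=seed)
        if m.excluded:
            continue
        points.append(
            TypePoint(
                trial_type=tt,
                n_targets_activated=float(m.means[0]),
                p_activated_bg=float(m.means[1]),
                p_suppressed_bg=float(m.means[2]),
                p_lick=float(licked.mean()),
                n_trials=len(idx),
                n_minority=m.n_minority,
            )
        )
    return points
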