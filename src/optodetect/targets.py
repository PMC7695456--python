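"""Target-zone classification of ROIs and trial-type network metrics.

A target zone is a cylinder of 10 um lateral radius around a
photostimulation coordinate, extending through the full axial range of
the imaging volume: an ROI is a target for a trial type if its centroid
lies within 10 um lateral distance of any of that type's zones,
irrespective of axial displacement.  Network proportions always use the
total neuron count (targets and background) as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.spatial.distance import cdist

from .thresholds import ACTIVATED, SUPPRESSED

__all__ = [
    "TARGET_RADIUS_UM",
    "NetworkMetrics",
    "TrendFit",
    "classify_rois",
    "count_activated_targets",
    "network_proportions",
    "linear_trend",
]

TARGET_RADIUS_UM: float = 10.0


@dataclass
class NetworkMetrics:
    """Per-trial-type activation/suppression proportions (trial-averaged)."""

    n_targets_activated: float
    p_activated_all: float
    p_suppressed_all: float
    p_activated_bg: float
    p_suppressed_bg: float
    act_sup_ratio: float  # NaN when p_suppressed_all == 0


@dataclass
class TrendFit:
    beta: float
    ci: tuple[float, float]
    r2: float
    p: float
    intercept: float


def classify_rois(
    roi_centroids_um: np.ndarray, zone_coords_um: np.ndarray, radius_um: float = TARGET_RADIUS_UM
) -> np.ndarray:
    """Boolean target mask: lateral distance <= radius to any zone (z ignored)."""
    cent = np.asarray(roi_centroids_um, dtype=float)
    zones = np.asarray(zone_coords_um, dtype=float)
    if zones.size == 0:
        raise ValueError("empty target-zone list for a go trial type")
    d = cdist(cent[:, :2], zones[:, :2])
    return d.min(axis=1) <= radius_um


def count_activated_targets(
    class_matrix: np.ndarray, target_mask: np.ndarray, trial_indices
) -> float:
    """Mean over trials of the count of activated target-labelled neurons."""
    cls = np.asarray(class_matrix)
    trial_indices = np.asarray(trial_indices, dtype=int)
    counts = (cls[np.asarray(target_mask, dtype=bool)][:, trial_indices] == ACTIVATED).sum(axis=0)
    return float(counts.mean()) if counts.size else 0.0


def per_trial_network_counts(class_matrix: np.ndarray, target_mask: np.ndarray):
    """Per-trial (n_act_all, n_sup_all, n_act_bg, n_sup_bg, n_act_targets) counts."""
    cls = np.asarray(class_matrix)
    tgt = np.asarray(target_mask, dtype=bool)
    act, sup = cls == ACTIVATED, cls == SUPPRESSED
    return {
        "act_all": act.sum(axis=0),
        "sup_all": sup.sum(axis=0),
        "act_bg": act[~tgt].sum(axis=0),
        "sup_bg": sup[~tgt].sum(axis=0),
        "act_targets": act[tgt].sum(axis=0),
    }


def network_proportions(
    class_matrix: np.ndarray, target_mask: np.ndarray, trial_indices=None
) -> NetworkMetrics:
    """Trial-averaged network metrics for one trial type.

    All-neuron proportions count every activated/suppressed neuron;
    background proportions exclude target-labelled neurons from the
    numerator only — the denominator is always the total neuron count.
    """
    cls = np.asarray(class_matrix)
    if trial_indices is not None:
        cls = cls[:, np.asarray(trial_indices, dtype=int)]
    n_neurons = cls.shape[0]
    counts = per_trial_network_counts(cls, target_mask)
    p_act = counts["act_all"].mean() / n_neurons
    p_sup = counts["sup_all"].mean() / n_neurons
    return NetworkMetrics(
        n_targets_activated=float(counts["act_targets"].mean()),
        p_activated_all=float(p_act),
        p_suppressed_all=float(p_sup),
        p_activated_bg=float(counts["act_bg"].mean() / n_neurons),
        p_suppressed_bg=float(counts["sup_bg"].mean() / n_neurons),
        act_sup_ratio=float(p_act / p_sup) if p_sup > 0 else np.nan,
    )


def linear_trend(x, y) -> TrendFit:
    """OLS slope of y on x with 95% CI, R^2 and two-sided p for slope = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 datapoints for a linear trend")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: trend undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)[1]
    return TrendFit(
        beta=float(res.params[1]),
        ci=(float(ci[0]), float(ci[1])),
        r2=float(res.rsquared),
        p=float(res.pvalues[1]),
        intercept=float(res.params[0]),
    )
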