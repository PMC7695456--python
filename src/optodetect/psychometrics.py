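"""Log-normal psychometric functions with fixed lapse and guess rates.

The model is

    psi(x; m, w, lam, gamma) = gamma + (1 - lam - gamma) * S(x; m, w)
    S(x; m, w) = Phi(C * (log(x) - m) / w),   C = Phi^-1(0.95) - Phi^-1(0.05)

so ``m`` is the log-stimulus midpoint of the scaled sigmoid ``S`` and ``w``
is its 5-95% width on the log-stimulus axis.  ``lam`` (lapse) and ``gamma``
(guess) are held fixed while ``(m, w)`` are fitted by weighted binomial
maximum likelihood.  The module also provides curve points (10/50/90%),
the slope at the midpoint, and permutation-based cross-validated
prediction of response rates from an arbitrary positive predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "C",
    "scaled_sigmoid",
    "psychometric",
    "PsychometricFit",
    "CurveSummary",
    "CrossvalResult",
    "fit_psychometric",
    "curve_points",
    "curve_summary",
    "slope_at_midpoint",
    "crossval_predict",
    "positive_stimulus",
]

#: 5-95% width constant of the scaled sigmoid.
C: float = float(stats.norm.ppf(0.95) - stats.norm.ppf(0.05))

_W_BOUNDS = (1e-3, 50.0)


def _check_rates(lam: float, gamma: float) -> None:
    if lam < 0 or gamma < 0 or lam + gamma >= 1:
        raise ValueError(
            f"require 0 <= lam, 0 <= gamma and lam + gamma < 1; got lam={lam}, gamma={gamma}"
        )


def scaled_sigmoid(x, m: float, w: float):
    """Evaluate the lapse/guess-free sigmoid S(x; m, w) = Phi(C (log x - m)/w)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("stimulus values must be strictly positive")
    if w <= 0:
        raise ValueError(f"width w must be positive, got {w}")
    return stats.norm.cdf(C * (np.log(x) - m) / w)


def psychometric(x, m: float, w: float, lam: float, gamma: float):
    """Evaluate psi(x) = gamma + (1 - lam - gamma) * S(x; m, w)."""
    _check_rates(lam, gamma)
    return gamma + (1.0 - lam - gamma) * scaled_sigmoid(x, m, w)


@dataclass
class PsychometricFit:
    """Maximum-likelihood fit of (m, w) with fixed lapse/guess rates."""

    m: float
    w: float
    lam: float
    gamma: float
    r2: float
    log_likelihood: float
    ci_m: tuple[float, float] | None = None
    ci_w: tuple[float, float] | None = None
    at_bound: bool = False
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_lick: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_trials: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, x):
        return psychometric(x, self.m, self.w, self.lam, self.gamma)


@dataclass
class CurveSummary:
    """10/50/90% points of the scaled curve and the psi slope at the midpoint."""

    x10: float
    x50: float
    x90: float
    slope50: float


@dataclass
class CrossvalResult:
    """Train/test R^2 distributions over permuted train:test splits."""

    r2_train: np.ndarray
    r2_test: np.ndarray
    p_train: float
    p_test: float
    n_perm: int
    train_frac: float


def _neg_log_likelihood(theta, logx, k, n, lam, gamma, weights):
    m, w = theta
    p = gamma + (1.0 - lam - gamma) * stats.norm.cdf(C * (logx - m) / w)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(weights * (k * np.log(p) + (n - k) * np.log1p(-p))))


def _fit_mw(logx, k, n, lam, gamma, weights, starts, polish=True):
    bounds = [(logx.min() - 10.0, logx.max() + 10.0), _W_BOUNDS]
    best = None
    for m0, w0 in starts:
        res = optimize.minimize(
            _neg_log_likelihood,
            x0=np.array([m0, w0]),
            args=(logx, k, n, lam, gamma, weights),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if not polish:
        return best
    # simplex polish: removes the ~1e-3 slack L-BFGS-B leaves near flat optima
    simplex = optimize.minimize(
        _neg_log_likelihood,
        x0=best.x,
        args=(logx, k, n, lam, gamma, weights),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    if simplex.fun <= best.fun and _W_BOUNDS[0] <= simplex.x[1] <= _W_BOUNDS[1]:
        best = simplex
    return best


def _default_starts(logx):
    span = max(logx.max() - logx.min(), 0.5)
    ms = np.linspace(logx.min(), logx.max(), 4)
    ws = [0.3 * span, span, 3.0 * span]
    return [(m0, min(max(w0, _W_BOUNDS[0]), _W_BOUNDS[1])) for m0 in ms for w0 in ws]


def _r_squared(p_obs, p_hat, weights):
    wmean = np.average(p_obs, weights=weights)
    ss_tot = float(np.sum(weights * (p_obs - wmean) ** 2))
    ss_res = float(np.sum(weights * (p_obs - p_hat) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def fit_psychometric(
    x,
    n_lick,
    n_trials,
    lambda_fixed: float,
    gamma_fixed: float,
    weights=None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PsychometricFit:
    """Fit (m, w) by weighted binomial maximum likelihood.

    Parameters
    ----------
    x : array_like
        Positive stimulus values (one per datapoint).
    n_lick, n_trials : array_like
        Response and trial counts per datapoint.
    lambda_fixed, gamma_fixed : float
        Fixed lapse and guess rates.
    weights : array_like, optional
        Per-datapoint weights (defaults to 1); typically the number of
        stimulus trials contributed by each session in aggregate fits.
    n_boot : int
        Bootstrap resamples of datapoints for 95% CIs on (m, w).
        ``0`` skips CI estimation.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(n_lick, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    if np.any(x <= 0):
        raise ValueError("stimulus values must be strictly positive")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct stimulus values")
    if np.any(n <= 0) or np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= n_lick <= n_trials and n_trials > 0")
    _check_rates(lambda_fixed, gamma_fixed)
    weights = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    weights = weights / weights.mean()  # scale-free: k*w and w give identical fits

    logx = np.log(x)
    res = _fit_mw(logx, k, n, lambda_fixed, gamma_fixed, weights, _default_starts(logx))
    m_hat, w_hat = float(res.x[0]), float(res.x[1])

    at_bound = w_hat >= _W_BOUNDS[1] - 1e-6 or w_hat <= _W_BOUNDS[0] + 1e-6
    if at_bound:
        warnings.warn(
            f"fitted width w={w_hat:.4g} hit an optimisation bound; data may be degenerate",
            stacklevel=2,
        )

    p_hat = gamma_fixed + (1 - lambda_fixed - gamma_fixed) * stats.norm.cdf(
        C * (logx - m_hat) / w_hat
    )
    r2 = _r_squared(k / n, p_hat, weights)

    ci_m = ci_w = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, 2))
        starts = [(m_hat, w_hat)] + _default_starts(logx)[::4]
        for b in range(n_boot):
            idx = rng.integers(0, len(x), size=len(x))
            if len(np.unique(logx[idx])) < 2:
                boot[b] = (np.nan, np.nan)
                continue
            r = _fit_mw(logx[idx], k[idx], n[idx], lambda_fixed, gamma_fixed, weights[idx], starts)
            boot[b] = r.x
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo_m, hi_m = np.nanpercentile(boot[:, 0], [2.5, 97.5])
            lo_w, hi_w = np.nanpercentile(boot[:, 1], [2.5, 97.5])
        ci_m, ci_w = (float(lo_m), float(hi_m)), (float(lo_w), float(hi_w))

    return PsychometricFit(
        m=m_hat,
        w=w_hat,
        lam=lambda_fixed,
        gamma=gamma_fixed,
        r2=r2,
        log_likelihood=-float(res.fun),
        ci_m=ci_m,
        ci_w=ci_w,
        at_bound=at_bound,
        x=x,
        n_lick=k,
        n_trials=n,
        weights=weights,
    )


def curve_points(fit: PsychometricFit | tuple[float, float], levels=(0.1, 0.5, 0.9)):
    """Stimulus values where the scaled curve S (not psi) reaches ``levels``.

    x_p = exp(m + (w / C) * Phi^-1(p)).
    """
    m, w = (fit.m, fit.w) if isinstance(fit, PsychometricFit) else fit
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0) or np.any(levels >= 1):
        raise ValueError("levels must lie strictly in (0, 1)")
    return np.exp(m + (w / C) * stats.norm.ppf(levels))


def slope_at_midpoint(fit: PsychometricFit, of: str = "psi") -> float:
    """Slope at the 50% point x50 = exp(m).

    ``of='psi'`` gives d(psi)/dx = (1 - lam - gamma) * C / (w * x50 * sqrt(2*pi)),
    the added response probability per unit stimulus; ``of='S'`` gives the
    slope of the scaled curve.
    """
    x50 = float(np.exp(fit.m))
    s = C / (fit.w * x50 * np.sqrt(2.0 * np.pi))
    if of == "S":
        return s
    if of == "psi":
        return (1.0 - fit.lam - fit.gamma) * s
    raise ValueError(f"of must be 'psi' or 'S', got {of!r}")


def curve_summary(fit: PsychometricFit) -> CurveSummary:
    x10, x50, x90 = curve_points(fit)
    return CurveSummary(x10=float(x10), x50=float(x50), x90=float(x90), slope50=slope_at_midpoint(fit))


def positive_stimulus(values, eps: float = 1e-4):
    """Shift proportion-valued predictors onto a positive stimulus axis (x = v + eps)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("predictor values must be non-negative")
    return values + eps


def crossval_predict(
    x,
    n_lick,
    n_trials,
    lambda_fixed: float,
    gamma_fixed: float,
    n_perm: int = 10_000,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> CrossvalResult:
    """Cross-validated prediction of response rate from a positive predictor.

    For each permutation the datapoints are split train:test (default
    80:20), (m, w) are re-fit on the training points with ``lambda_fixed``
    and ``gamma_fixed`` held at values computed once from all data, and
    R^2 is evaluated on both partitions.  ``p_train``/``p_test`` are the
    fractions of permutations with R^2 <= 0.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(n_lick, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 datapoints for cross-validation")
    if np.any(x <= 0):
        raise ValueError("predictor must be positive (apply positive_stimulus first)")
    _check_rates(lambda_fixed, gamma_fixed)

    logx = np.log(x)
    ones = np.ones_like(x)
    full = _fit_mw(logx, k, n, lambda_fixed, gamma_fixed, ones, _default_starts(logx))
    warm = [(float(full.x[0]), float(full.x[1])), _default_starts(logx)[5]]

    n_train = int(round(train_frac * len(x)))
    n_train = min(max(n_train, 2), len(x) - 1)

    rng = np.random.default_rng(seed)
    r2_train = np.empty(n_perm)
    r2_test = np.empty(n_perm)
    p_obs = k / n
    for i in range(n_perm):
        for _ in range(100):  # reshuffle degenerate splits
            perm = rng.permutation(len(x))
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(logx[tr])) >= 2:
                break
        else:
            raise ValueError("could not draw a train split with >= 2 distinct predictor values")
        res = _fit_mw(logx[tr], k[tr], n[tr], lambda_fixed, gamma_fixed, ones[tr], warm, polish=False)
        m_i, w_i = res.x
        pred = gamma_fixed + (1 - lambda_fixed - gamma_fixed) * stats.norm.cdf(
            C * (logx - m_i) / w_i
        )
        r2_train[i] = _r_squared(p_obs[tr], pred[tr], ones[tr])
        r2_test[i] = _r_squared(p_obs[te], pred[te], ones[te])

    ok_tr, ok_te = np.isfinite(r2_train), np.isfinite(r2_test)
    return CrossvalResult(
        r2_train=r2_train,
        r2_test=r2_test,
        p_train=float(np.mean(r2_train[ok_tr] <= 0)) if ok_tr.any() else np.nan,
        p_test=float(np.mean(r2_test[ok_te] <= 0)) if ok_te.any() else np.nan,
        n_perm=n_perm,
        train_frac=train_frac,
    )
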