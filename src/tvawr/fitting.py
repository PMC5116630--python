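"""Maximum-likelihood estimation of the whole-report model.

One fit consumes the scored trials of a single participant x device x
session and returns the three visual processing components: threshold of
conscious perception (mean and trial-to-trial SD), total processing speed
``C``, and the capacity distribution over 1..6 letters.

The 8 free parameters are optimized in an unconstrained space (identity
for the threshold mean, log for its SD and for ``C``, stick-breaking
log-odds for the five free capacity probabilities) with a multi-start
quasi-Newton search, since the likelihood surface can be multimodal for
small sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model import N_ITEMS, TVAParams, _log_likelihood_counts

__all__ = ["FitConfig", "FitResult", "to_unconstrained", "from_unconstrained", "fit_mle"]

N_PARAMS = 8  # t0_mean, log t0_sd, log C, 5 stick-breaking logits

_EPS = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings and parameter bounds."""

    n_starts: int = 8
    t0_mean_bounds: tuple = (0.0, 200.0)
    t0_sd_bounds: tuple = (0.01, 100.0)
    C_bounds: tuple = (1.0, 500.0)
    quad_nodes: int = 64
    seed: int = 0
    tol: float = 1e-8

    def __post_init__(self):
        for lo, hi in (self.t0_mean_bounds, self.t0_sd_bounds, self.C_bounds):
            if not lo < hi:
                raise ValueError("bounds must be ordered (lo < hi)")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: TVAParams
    loglik: float
    converged: bool
    n_trials: int
    start_index: int
    diagnostics: tuple = ()
    identifiable: bool = True


def _stick_break(logits: np.ndarray) -> np.ndarray:
    """Map 5 unconstrained logits to a 6-point probability vector."""
    probs = np.empty(N_ITEMS)
    remaining = 1.0
    for i in range(N_ITEMS - 1):
        v = expit(logits[i])
        probs[i] = v * remaining
        remaining *= 1.0 - v
    probs[N_ITEMS - 1] = remaining
    return probs


def _stick_break_inverse(k_probs: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(k_probs, dtype=float), _EPS, 1.0)
    p = p / p.sum()
    logits = np.empty(N_ITEMS - 1)
    remaining = 1.0
    for i in range(N_ITEMS - 1):
        logits[i] = logit(np.clip(p[i] / remaining, _EPS, 1.0 - _EPS))
        remaining -= p[i]
    return logits


def to_unconstrained(params: TVAParams, config: FitConfig = FitConfig()) -> np.ndarray:
    """Map valid parameters to the unconstrained optimization space."""
    x = np.empty(N_PARAMS)
    x[0] = params.t0_mean
    x[1] = np.log(params.t0_sd) if params.t0_sd > 0 else np.log(config.t0_sd_bounds[0])
    x[2] = np.log(params.C)
    x[3:] = _stick_break_inverse(params.k_probs)
    return x


def from_unconstrained(x: np.ndarray, config: FitConfig = FitConfig()) -> TVAParams:
    """Map any real 8-vector to valid parameters (inverse of to_unconstrained
    on the interior of the bounds)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (N_PARAMS,) or not np.all(np.isfinite(x)):
        raise ValueError(f"expected a finite vector of length {N_PARAMS}")
    t0_mean = float(np.clip(x[0], *config.t0_mean_bounds))
    # clip in log space so extreme optimizer excursions cannot overflow exp
    t0_sd = float(np.exp(np.clip(x[1], *np.log(config.t0_sd_bounds))))
    C = float(np.exp(np.clip(x[2], *np.log(config.C_bounds))))
    return TVAParams(t0_mean=t0_mean, t0_sd=t0_sd, C=C, k_probs=_stick_break(x[3:]))


def _moment_start(exposures: np.ndarray, scores: np.ndarray, config: FitConfig) -> np.ndarray:
    """Moment-based initial guess from the mean-score-vs-duration curve."""
    uniq = np.unique(exposures)
    means = np.array([scores[exposures == d].mean() for d in uniq])

    # threshold: just below the shortest duration showing real performance
    above = uniq[means > 0.1]
    t0_init = 0.7 * above[0] if len(above) else 0.5 * uniq[-1]
    t0_init = np.clip(t0_init, config.t0_mean_bounds[0] + 1.0, config.t0_mean_bounds[1] - 1.0)

    # speed: initial slope of mean score vs duration, ~C/1000 per ms near threshold
    slopes = np.diff(means) / np.diff(uniq)
    C_init = np.clip(1000.0 * max(slopes.max(initial=0.0), 1e-3), 5.0, 400.0)

    # capacity: smoothed histogram of scores at the two longest durations
    long_scores = scores[np.isin(exposures, uniq[-2:])]
    hist = np.bincount(long_scores, minlength=N_ITEMS + 1).astype(float)
    hist[1] += hist[0]  # zero scores at long exposures fold into capacity 1
    k_init = (hist[1:] + 0.5) / (hist[1:] + 0.5).sum()

    params = TVAParams(t0_mean=float(t0_init), t0_sd=10.0, C=float(C_init), k_probs=k_init)
    return to_unconstrained(params, config)


_JITTER_SCALE = np.array([5.0, 0.4, 0.4, 0.8, 0.8, 0.8, 0.8, 0.8])


def fit_mle(trials, config: FitConfig = FitConfig()) -> FitResult:
    """Fit the whole-report model to one session's scored trials.

    Practice trials (block 0) are excluded.  Requires at least 30 scored
    trials spanning at least 3 distinct exposure durations.  Runs
    ``config.n_starts`` local optimizations from a moment-based initial
    guess plus jittered copies (jitter seeded by ``config.seed``) and
    returns the best; ties between starts break toward the lowest start
    index, making the result deterministic for fixed inputs and config.
    """
    scored = [t for t in trials if t.block != 0]
    if any(t.n_displayed != N_ITEMS for t in scored):
        raise ValueError(f"all trials must display {N_ITEMS} letters")
    exposures = np.array([t.exposure_ms for t in scored], dtype=float)
    scores = np.array([t.n_correct for t in scored], dtype=int)
    if len(scored) < 30 or len(np.unique(exposures)) < 3:
        raise ValueError(
            "fit_mle needs >= 30 non-practice trials spanning >= 3 distinct durations"
        )

    if scores.max() == 0:
        # no letter ever reported: C is not identifiable, pin it at the lower bound
        params = TVAParams(
            t0_mean=float(exposures.max()), t0_sd=config.t0_sd_bounds[0],
            C=config.C_bounds[0], k_probs=np.eye(N_ITEMS)[0],
        )
        ll = _log_likelihood_counts(params, exposures, scores, config.quad_nodes)
        return FitResult(params, ll, converged=False, n_trials=len(scored),
                         start_index=-1, identifiable=False)

    def negloglik(x):
        return -_log_likelihood_counts(
            from_unconstrained(x, config), exposures, scores, config.quad_nodes
        )

    x0 = _moment_start(exposures, scores, config)
    rng = np.random.default_rng(config.seed)
    starts = [x0] + [
        x0 + rng.normal(scale=_JITTER_SCALE) for _ in range(config.n_starts - 1)
    ]

    best = None
    diagnostics = []
    for idx, start in enumerate(starts):
        res = minimize(negloglik, start, method="L-BFGS-B", tol=config.tol)
        diagnostics.append(float(res.fun))
        if best is None or res.fun < best[1].fun:
            best = (idx, res)
    idx, res = best
    return FitResult(
        params=from_unconstrained(res.x, config),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_trials=len(scored),
        start_index=idx,
        diagnostics=tuple(diagnostics),
    )
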