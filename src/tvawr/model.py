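"""Analytic whole-report model from the theory of visual attention (TVA).

Six masked letters race for encoding into a limited-capacity visual working
memory.  Processing of every item starts once the exposure exceeds a
perceptual threshold ``t0`` that varies from trial to trial as a normal
variate (shared by all items within a trial); after the threshold each item
finishes after an exponential waiting time with rate ``C / 6`` (equal
attentional weights), so the marginal finishing time of a single item is
ex-Gaussian.  Of the items that finish within the effective exposure, at
most ``K`` are retained, where ``K`` is drawn per trial from a distribution
over 1..6.  The observable is the number of correctly reported letters
(0..6); this module computes its probability mass function and the
log-likelihood of trial data.

Units: durations in milliseconds; the total processing rate ``C`` in
items/second externally, converted to items/ms internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb, log_ndtr, ndtr

__all__ = [
    "LETTER_SET",
    "N_ITEMS",
    "TVAParams",
    "ScoreDistribution",
    "TrialRecord",
    "item_rate",
    "conditional_score_pmf",
    "score_pmf",
    "marginal_item_encoding_prob",
    "log_likelihood",
    "expected_K",
    "expected_score",
]

#: The 20 capital letters used as whole-report stimuli.
LETTER_SET = "ABDEFGHJKLMNOPRSTUVX"

#: Number of letters displayed per trial.
N_ITEMS = 6

_SCORES = np.arange(N_ITEMS + 1)
_BINOM_COEF = comb(N_ITEMS, _SCORES)  # C(6, m) for m = 0..6

#: Probability floor applied before taking logs in the likelihood.
PROB_FLOOR = 1e-300


def _as_k_probs(k_probs) -> np.ndarray:
    p = np.asarray(k_probs, dtype=float)
    if p.shape != (N_ITEMS,):
        raise ValueError(f"k_probs must have length {N_ITEMS}, got shape {p.shape}")
    if np.any(p < -1e-12):
        raise ValueError("k_probs entries must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"k_probs must sum to 1 (got {p.sum()!r})")
    return np.clip(p, 0.0, None)


@dataclass(frozen=True)
class TVAParams:
    """Free parameters of the whole-report model.

    Parameters
    ----------
    t0_mean : float
        Mean threshold of conscious perception, ms.
    t0_sd : float
        Across-trial standard deviation of the threshold, ms (>= 0).
    C : float
        Total visual processing speed, items/second (> 0).
    k_probs : array-like of 6 floats
        Probability that the visual working memory capacity equals
        1, 2, ..., 6 on a given trial.  Must sum to 1; by convention the
        probability of capacity 6 is one minus the sum of the first five.
    """

    t0_mean: float
    t0_sd: float
    C: float
    k_probs: np.ndarray = field(default_factory=lambda: np.full(N_ITEMS, 1.0 / N_ITEMS))

    def __post_init__(self):
        if not np.isfinite(self.t0_mean):
            raise ValueError("t0_mean must be finite")
        if not (self.t0_sd >= 0):
            raise ValueError("t0_sd must be >= 0")
        if not (self.C > 0):
            raise ValueError("C must be > 0")
        object.__setattr__(self, "k_probs", _as_k_probs(self.k_probs))

    @property
    def expected_K(self) -> float:
        """Mean visual working memory capacity, in letters."""
        return float(np.arange(1, N_ITEMS + 1) @ self.k_probs)


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability mass over the number of correctly reported letters (0..6)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_ITEMS + 1,):
            raise ValueError("ScoreDistribution needs 7 probabilities")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("ScoreDistribution entries must be a probability vector")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))

    def __getitem__(self, m: int) -> float:
        return float(self.probs[m])

    @property
    def mean(self) -> float:
        return float(_SCORES @ self.probs)


@dataclass
class TrialRecord:
    """One whole-report trial.

    ``block`` 0 marks the practice block, excluded from model fitting.
    ``n_errors`` counts erroneously reported letters; an empty report is
    not an error.
    """

    participant_id: str
    device: str
    session: int
    block: int
    trial_index: int
    exposure_ms: float
    n_displayed: int = N_ITEMS
    displayed_letters: str = ""
    reported_letters: str = ""
    n_correct: int = 0
    n_errors: int = 0
    exposure_target_ms: float | None = None

    def __post_init__(self):
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        if self.block < 0 or self.trial_index < 1:
            raise ValueError("block must be >= 0 and trial_index >= 1")
        if not (0 <= self.n_correct <= self.n_displayed):
            raise ValueError("n_correct must lie in 0..n_displayed")
        if self.n_errors < 0:
            raise ValueError("n_errors must be >= 0")
        if self.displayed_letters:
            if len(set(self.displayed_letters)) != len(self.displayed_letters):
                raise ValueError("displayed letters must be distinct")
            if not set(self.displayed_letters) <= set(LETTER_SET):
                raise ValueError(f"displayed letters must come from {LETTER_SET!r}")
        if self.reported_letters and self.n_correct + self.n_errors != len(self.reported_letters):
            raise ValueError("n_correct + n_errors must equal the number of reported letters")

    @property
    def is_practice(self) -> bool:
        return self.block == 0


def item_rate(params: TVAParams, n_items: int = N_ITEMS) -> float:
    """Per-item exponential processing rate in 1/ms.

    With equal attentional weights each of ``n_items`` items receives
    ``C / n_items`` items/s of the total processing capacity.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    return (params.C / n_items) / 1000.0


def _conditional_pmf_from_tau(k_probs: np.ndarray, v: float, tau) -> np.ndarray:
    """Score pmf rows for effective exposures ``tau`` (ms), vectorized.

    Given the threshold, the number of items finishing within ``tau`` is
    ``B ~ Binomial(6, 1 - exp(-v * tau))`` and the score is ``min(K, B)``.
    Rows for ``tau <= 0`` are a point mass at score 0.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    F = np.where(tau > 0, -np.expm1(-v * np.clip(tau, 0.0, None)), 0.0)
    F = np.clip(F, 0.0, 1.0)
    # binomial pmf b[i, m] = C(6,m) F^m (1-F)^(6-m)
    b = _BINOM_COEF * F[:, None] ** _SCORES * (1.0 - F[:, None]) ** (N_ITEMS - _SCORES)
    # survival S[i, m] = P(B >= m)
    S = np.cumsum(b[:, ::-1], axis=1)[:, ::-1]
    # P(K > m) for m = 0..6 (K supported on 1..6)
    k_tail = np.concatenate([[1.0], 1.0 - np.cumsum(k_probs)])
    k_tail = np.clip(k_tail, 0.0, 1.0)
    pmf = b * k_tail[None, :]
    # add P(K = m) * P(B >= m) for m = 1..6
    pmf[:, 1:] += k_probs[None, :] * S[:, 1:]
    return pmf


def conditional_score_pmf(params: TVAParams, exposure_ms: float, t0_value: float) -> ScoreDistribution:
    """Score distribution conditional on a realized threshold ``t0_value``."""
    if not np.isfinite(exposure_ms):
        raise ValueError("exposure_ms must be finite")
    v = item_rate(params)
    pmf = _conditional_pmf_from_tau(params.k_probs, v, exposure_ms - t0_value)[0]
    return ScoreDistribution(pmf / pmf.sum())


def _score_pmf_rows(params: TVAParams, exposures_ms: np.ndarray, n_nodes: int) -> np.ndarray:
    """Marginal score pmfs for several exposures, one row each.

    Integrates the conditional pmf over ``t0 ~ N(t0_mean, t0_sd)`` by
    Gauss-Hermite quadrature; the threshold draw is shared by all six items
    within a trial, so items are conditionally (not marginally) independent.
    """
    exposures_ms = np.atleast_1d(np.asarray(exposures_ms, dtype=float))
    v = item_rate(params)
    if params.t0_sd == 0:
        return _conditional_pmf_from_tau(params.k_probs, v, exposures_ms - params.t0_mean)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    t0 = params.t0_mean + np.sqrt(2.0) * params.t0_sd * nodes
    w = weights / np.sqrt(np.pi)
    tau = exposures_ms[:, None] - t0[None, :]  # (n_exp, n_nodes)
    cond = _conditional_pmf_from_tau(params.k_probs, v, tau.ravel())
    cond = cond.reshape(tau.shape + (N_ITEMS + 1,))
    pmf = np.einsum("j,ijm->im", w, cond)
    return pmf / pmf.sum(axis=1, keepdims=True)


def score_pmf(params: TVAParams, exposure_ms: float, n_nodes: int = 64) -> ScoreDistribution:
    """Marginal score distribution at a given exposure duration.

    The normal threshold is integrated out with ``n_nodes``-point
    Gauss-Hermite quadrature (exact conditional evaluation when
    ``t0_sd == 0``).  The normal is not truncated: draws above the exposure
    yield score 0, negative draws act like a longer effective exposure.
    """
    if n_nodes < 8:
        raise ValueError("n_nodes must be >= 8")
    return ScoreDistribution(_score_pmf_rows(params, exposure_ms, n_nodes)[0])


def marginal_item_encoding_prob(params: TVAParams, exposure_ms: float) -> float:
    """Probability that a single item finishes within the exposure.

    The item's finishing time ``t0 + X`` (``X`` exponential with the
    per-item rate) is ex-Gaussian; this evaluates its CDF
    ``Phi((t-mu)/sigma) - exp(-v(t-mu) + v^2 sigma^2 / 2) * Phi((t-mu-v sigma^2)/sigma)``
    in log-space for numerical stability.
    """
    v = item_rate(params)
    mu, sigma = params.t0_mean, params.t0_sd
    t = float(exposure_ms)
    if sigma == 0:
        return max(0.0, float(-np.expm1(-v * (t - mu)))) if t > mu else 0.0
    z1 = (t - mu) / sigma
    log_term2 = -v * (t - mu) + 0.5 * v * v * sigma * sigma + log_ndtr((t - mu - v * sigma * sigma) / sigma)
    p = ndtr(z1) - np.exp(log_term2)
    return float(np.clip(p, 0.0, 1.0))


def log_likelihood(params: TVAParams, trials, n_nodes: int = 64) -> float:
    """Log-likelihood of the observed correct-report counts.

    Score pmfs are computed once per unique exposure duration and reused.
    Probabilities are floored at 1e-300 before the log, so the result is
    finite for any valid parameters.  Practice trials are the caller's
    responsibility to exclude.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("log_likelihood needs at least one trial")
    exposures = np.array([t.exposure_ms for t in trials])
    scores = np.array([t.n_correct for t in trials])
    return _log_likelihood_counts(params, exposures, scores, n_nodes)


def _log_likelihood_counts(params, exposures, scores, n_nodes: int = 64) -> float:
    """Vectorized likelihood kernel on parallel exposure/score arrays."""
    uniq, inv = np.unique(exposures, return_inverse=True)
    pmf = _score_pmf_rows(params, uniq, n_nodes)
    probs = pmf[inv, scores]
    return float(np.log(np.clip(probs, PROB_FLOOR, None)).sum())


def expected_K(k_probs) -> float:
    """Expected visual working memory capacity, sum of k * P(K = k)."""
    p = _as_k_probs(k_probs)
    return float(np.arange(1, N_ITEMS + 1) @ p)


def expected_score(params: TVAParams, exposure_ms: float, n_nodes: int = 64) -> float:
    """Mean number of correctly reported letters at a given exposure."""
    return score_pmf(params, exposure_ms, n_nodes).mean
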