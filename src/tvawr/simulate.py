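"""Synthetic whole-report data with the structure of a two-device reliability study.

Emulates a cohort of participants who each complete two whole-report
sessions on a CRT monitor and two on a head-mounted display (HMD), one week
apart: 9 blocks of 18 trials per session (plus an 18-trial practice block)
at six exposure durations, six letters per trial drawn without replacement
from a 20-letter set, each followed by a 500 ms pattern mask.

Across participants the model components (threshold mean, processing speed,
expected memory capacity) vary normally; session-1 and session-2 true
values are bivariate normal with a configurable test-retest correlation,
a session shift emulating practice effects, and a device offset.  Reported
letters are corrupted at a configurable rate to emulate the instructed
10-20% error band; errors never enter the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom

from .model import LETTER_SET, N_ITEMS, TVAParams, TrialRecord, item_rate

__all__ = [
    "DesignSpec",
    "ComponentPopulation",
    "CohortSpec",
    "k_probs_from_expected_K",
    "simulate_trial",
    "simulate_scores",
    "simulate_session",
    "simulate_cohort",
    "simulate_cohort_truth",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("t0_mean", "C", "expected_K")

#: Admissible ranges for the latent per-participant components; draws
#: outside are rejected and redrawn.
COMPONENT_BOUNDS = {"t0_mean": (0.0, 200.0), "C": (1.0, 500.0), "expected_K": (1.0, 6.0)}


@dataclass(frozen=True)
class DesignSpec:
    """Structure of one whole-report session on one device."""

    device: str
    exposure_durations_ms: tuple
    target_durations_ms: tuple | None = None
    trials_per_duration: int = 27
    n_blocks: int = 9
    trials_per_block: int = 18
    include_practice: bool = True
    n_items: int = N_ITEMS
    letter_set: str = LETTER_SET
    mask_ms: float = 500.0

    def __post_init__(self):
        durations = tuple(float(d) for d in self.exposure_durations_ms)
        if len(durations) != 6 or any(d <= 0 for d in durations):
            raise ValueError("exposure_durations_ms must be 6 positive durations")
        if list(durations) != sorted(durations):
            raise ValueError("exposure_durations_ms must be sorted")
        if self.n_blocks * self.trials_per_block != 6 * self.trials_per_duration:
            raise ValueError(
                "design mismatch: n_blocks * trials_per_block must equal "
                "6 * trials_per_duration"
            )
        object.__setattr__(self, "exposure_durations_ms", durations)
        if self.target_durations_ms is not None:
            object.__setattr__(
                self, "target_durations_ms", tuple(float(d) for d in self.target_durations_ms)
            )

    @property
    def n_trials(self) -> int:
        return 6 * self.trials_per_duration

    def scaled(self, trials_per_duration: int) -> "DesignSpec":
        """A reduced-volume variant keeping the block arithmetic consistent."""
        return replace(
            self,
            trials_per_duration=trials_per_duration,
            n_blocks=6,
            trials_per_block=trials_per_duration,
        )


@dataclass(frozen=True)
class ComponentPopulation:
    """Population description of one visual processing component.

    ``mean``/``sd`` describe session 1 on the baseline (HMD) device;
    ``session_shift`` is added to the session-2 mean (practice effect) and
    ``device_shift`` to both sessions on the CRT.  ``rho`` is the
    test-retest correlation of the true values across sessions.
    """

    mean: float
    sd: float
    rho: float
    session_shift: float = 0.0
    device_shift: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of the synthetic cohort.

    Defaults emulate the reliability study's descriptives: 44 participants,
    thresholds near 15 ms that drop with practice, processing speeds near
    80 letters/s that rise (markedly on the HMD), capacities near 3.7
    letters, and an 11% letter-report error rate.
    """

    n_participants: int = 44
    t0_mean: ComponentPopulation = field(
        default_factory=lambda: ComponentPopulation(
            mean=13.4, sd=5.2, rho=0.6, session_shift=-2.5, device_shift=4.0
        )
    )
    C: ComponentPopulation = field(
        default_factory=lambda: ComponentPopulation(
            mean=81.0, sd=36.0, rho=0.6, session_shift=19.0, device_shift=-9.0
        )
    )
    expected_K: ComponentPopulation = field(
        default_factory=lambda: ComponentPopulation(
            mean=3.7, sd=0.7, rho=0.8, session_shift=0.08, device_shift=-0.28
        )
    )
    t0_trial_sd_ms: float = 10.0
    error_rate: float = 0.11
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.error_rate <= 0.5:
            raise ValueError("error_rate must lie in [0, 0.5]")
        if self.t0_trial_sd_ms < 0:
            raise ValueError("t0_trial_sd_ms must be >= 0")

    def component(self, name: str) -> ComponentPopulation:
        if name not in COMPONENTS:
            raise KeyError(name)
        return getattr(self, name)


def k_probs_from_expected_K(target: float) -> np.ndarray:
    """Capacity distribution with a given mean, as a shifted binomial.

    ``K = 1 + Binomial(5, q)`` with ``q = (target - 1) / 5`` is the
    single-parameter family used to map a scalar capacity target to the
    six-point distribution; its mean is exactly ``target`` for targets in
    [1, 6].
    """
    target = float(np.clip(target, 1.0, 6.0))
    q = (target - 1.0) / 5.0
    return binom.pmf(np.arange(N_ITEMS), N_ITEMS - 1, q)


def simulate_trial(
    params: TVAParams,
    exposure_ms: float,
    rng: np.random.Generator,
    *,
    error_rate: float = 0.0,
    participant_id: str = "sim",
    device: str = "SIM",
    session: int = 1,
    block: int = 1,
    trial_index: int = 1,
    letter_set: str = LETTER_SET,
    exposure_target_ms: float | None = None,
) -> TrialRecord:
    """Simulate one whole-report trial by running the race explicitly.

    Draws the trial threshold, six exponential finishing offsets and a
    capacity ``K``; the first ``min(K, number finished in time)`` items by
    finishing order are encoded.  Each encoded letter is independently
    corrupted to a random non-displayed letter with probability
    ``error_rate``; corrupted letters count as errors, not as correct.
    """
    letters = rng.choice(list(letter_set), size=N_ITEMS, replace=False)
    t0 = rng.normal(params.t0_mean, params.t0_sd)
    tau = exposure_ms - t0
    n_correct = 0
    reported: list[str] = []
    if tau > 0:
        finish = rng.exponential(1.0 / item_rate(params), size=N_ITEMS)
        K = int(rng.choice(np.arange(1, N_ITEMS + 1), p=params.k_probs))
        finished_idx = np.argsort(finish)[: min(K, int(np.sum(finish <= tau)))]
        encoded = [str(letters[i]) for i in finished_idx]
        non_displayed = [c for c in letter_set if c not in set(letters)]
        for letter in encoded:
            if error_rate > 0 and rng.random() < error_rate:
                reported.append(str(rng.choice(non_displayed)))
            else:
                reported.append(letter)
                n_correct += 1
    return TrialRecord(
        participant_id=participant_id,
        device=device,
        session=session,
        block=block,
        trial_index=trial_index,
        exposure_ms=float(exposure_ms),
        n_displayed=N_ITEMS,
        displayed_letters="".join(str(c) for c in letters),
        reported_letters="".join(reported),
        n_correct=n_correct,
        n_errors=len(reported) - n_correct,
        exposure_target_ms=exposure_target_ms,
    )


def simulate_scores(
    params: TVAParams, exposure_ms: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of ``n`` correct-report counts at one exposure.

    Uses the race's sufficient statistics (number of items finished within
    the effective exposure is binomial given the threshold) instead of
    per-letter bookkeeping; serves as the Monte-Carlo oracle for the
    analytic score distribution.
    """
    t0 = rng.normal(params.t0_mean, params.t0_sd, size=n)
    tau = np.clip(exposure_ms - t0, 0.0, None)
    F = -np.expm1(-item_rate(params) * tau)
    B = rng.binomial(N_ITEMS, F)
    K = rng.choice(np.arange(1, N_ITEMS + 1), p=params.k_probs, size=n)
    return np.minimum(K, B)


def _session_durations(design: DesignSpec, rng: np.random.Generator, practice: bool) -> np.ndarray:
    if practice:
        reps = int(np.ceil(design.trials_per_block / 6))
        durations = np.tile(design.exposure_durations_ms, reps)[: design.trials_per_block]
    else:
        durations = np.repeat(design.exposure_durations_ms, design.trials_per_duration)
    return rng.permutation(durations)


def simulate_session(
    params: TVAParams,
    design: DesignSpec,
    rng: np.random.Generator,
    *,
    error_rate: float = 0.0,
    participant_id: str = "sim",
    session: int = 1,
) -> list[TrialRecord]:
    """Simulate a full session: practice block 0, then the scored blocks.

    Durations are balanced within the session (``trials_per_duration`` each)
    and shuffled uniformly; letters are drawn without replacement per trial.
    """
    target_of = {}
    if design.target_durations_ms is not None:
        target_of = dict(zip(design.exposure_durations_ms, design.target_durations_ms))
    trials = []
    if design.include_practice:
        for i, dur in enumerate(_session_durations(design, rng, practice=True), start=1):
            trials.append(
                simulate_trial(
                    params, dur, rng,
                    error_rate=error_rate, participant_id=participant_id,
                    device=design.device, session=session, block=0, trial_index=i,
                    letter_set=design.letter_set, exposure_target_ms=target_of.get(dur),
                )
            )
    durations = _session_durations(design, rng, practice=False)
    for j, dur in enumerate(durations):
        block = j // design.trials_per_block + 1
        idx = j % design.trials_per_block + 1
        trials.append(
            simulate_trial(
                params, dur, rng,
                error_rate=error_rate, participant_id=participant_id,
                device=design.device, session=session, block=block, trial_index=idx,
                letter_set=design.letter_set, exposure_target_ms=target_of.get(dur),
            )
        )
    return trials


def _draw_component(pop: ComponentPopulation, bounds, is_crt: bool, rng) -> tuple[float, float, int]:
    """One participant's (session1, session2) true values, redrawn until in bounds."""
    m1 = pop.mean + (pop.device_shift if is_crt else 0.0)
    m2 = m1 + pop.session_shift
    lo, hi = bounds
    for attempt in range(1000):
        z1, z2 = rng.standard_normal(2)
        # Cholesky factor of the bivariate correlation; exact at rho = +/-1
        s1 = m1 + pop.sd * z1
        s2 = m2 + pop.sd * (pop.rho * z1 + np.sqrt(1.0 - pop.rho**2) * z2)
        if lo <= s1 <= hi and lo <= s2 <= hi:
            return float(s1), float(s2), attempt
    raise RuntimeError("component redraw limit exceeded; check CohortSpec bounds")


def _participant_truth(spec: CohortSpec, devices, rng) -> tuple[list[dict], int]:
    """True component values for one participant on every device x session."""
    rows = []
    n_redraws = 0
    for device in devices:
        is_crt = device.upper() == "CRT"
        values = {}
        for name in COMPONENTS:
            s1, s2, redraws = _draw_component(
                spec.component(name), COMPONENT_BOUNDS[name], is_crt, rng
            )
            values[name] = (s1, s2)
            n_redraws += redraws
        for session in (1, 2):
            rows.append(
                {
                    "device": device, "session": session,
                    **{name: values[name][session - 1] for name in COMPONENTS},
                    "t0_sd": spec.t0_trial_sd_ms, "error_rate": spec.error_rate,
                }
            )
    return rows, n_redraws


def _participant_streams(spec: CohortSpec, seed: int | None):
    if seed is None:
        seed = spec.seed
    return np.random.SeedSequence(seed).spawn(spec.n_participants)


def _pid(i: int, n: int) -> str:
    # fixed width so identifiers do not depend on the cohort size
    return f"P{i + 1:03d}"


def simulate_cohort_truth(spec: CohortSpec, devices=("HMD", "CRT"), seed: int | None = None):
    """Draw only the cohort's true component table, no trials.

    Uses the same random substreams as :func:`simulate_cohort`, so for a
    given seed the returned table equals the ``truth`` that
    ``simulate_cohort`` would produce with those devices.
    """
    import pandas as pd

    rows = []
    n_redraws = 0
    for i, ss in enumerate(_participant_streams(spec, seed)):
        rng_truth = np.random.default_rng(ss.spawn(2)[0])
        participant_rows, redraws = _participant_truth(spec, devices, rng_truth)
        n_redraws += redraws
        for row in participant_rows:
            rows.append({"participant_id": _pid(i, spec.n_participants), **row})
    if n_redraws:
        logger.info("cohort truth: %d out-of-bounds component draws redrawn", n_redraws)
    return pd.DataFrame(
        rows,
        columns=["participant_id", "device", "session", *COMPONENTS, "t0_sd", "error_rate"],
    )


def simulate_cohort(
    spec: CohortSpec,
    designs: dict[str, DesignSpec],
    seed: int | None = None,
):
    """Simulate the full two-device, two-session cohort.

    Each participant's true component values are drawn from per-component
    bivariate normals across sessions (correlation ``rho``, session-2 mean
    shifted by ``session_shift``; CRT means offset by ``device_shift``),
    then all four sessions are simulated on the device-specific duration
    sets.  Per-participant random substreams (split further into a truth
    stream and a trial stream) make participant ``i``'s data invariant to
    the total cohort size and the truth table reproducible without
    simulating trials.

    Returns ``(trials, truth)`` where ``truth`` is a pandas DataFrame of
    the generating component values, one row per
    participant x device x session.
    """
    import pandas as pd

    devices = tuple(designs)
    trials: list[TrialRecord] = []
    truth_rows = []
    n_redraws = 0
    for i, ss in enumerate(_participant_streams(spec, seed)):
        pid = _pid(i, spec.n_participants)
        truth_ss, trial_ss = ss.spawn(2)
        rng_truth = np.random.default_rng(truth_ss)
        rng_trials = np.random.default_rng(trial_ss)
        participant_rows, redraws = _participant_truth(spec, devices, rng_truth)
        n_redraws += redraws
        for row in participant_rows:
            params = TVAParams(
                t0_mean=row["t0_mean"], t0_sd=spec.t0_trial_sd_ms, C=row["C"],
                k_probs=k_probs_from_expected_K(row["expected_K"]),
            )
            trials.extend(
                simulate_session(
                    params, designs[row["device"]], rng_trials,
                    error_rate=spec.error_rate, participant_id=pid, session=row["session"],
                )
            )
            truth_rows.append({"participant_id": pid, **row})
    if n_redraws:
        logger.info("simulate_cohort: %d out-of-bounds component draws redrawn", n_redraws)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
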