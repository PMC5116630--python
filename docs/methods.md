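# Methods

## The whole-report model

A trial presents six distinct letters (from the 20-letter set
ABDEFGHJKLMNOPRSTUVX) for an exposure of t ms, each immediately followed by
a 500 ms pattern mask that terminates processing. The model assumes:

1. **Threshold.** Visual processing starts only after a threshold
   t₀ ~ N(μ_t₀, σ_t₀) drawn once per trial and shared by all six letters.
   The normal is not truncated: a draw above the exposure yields score 0,
   and a negative draw acts like a longer effective exposure. Trial-level
   (rather than per-item) threshold variability is what makes the marginal
   finishing time of each item ex-Gaussian while keeping items
   conditionally independent given t₀.
2. **Race.** After the threshold, each letter finishes after an exponential
   waiting time with rate v = C/6 per ms (C in letters/s divided by 6000) —
   equal attentional weights across six homogeneous letters. Given t₀, the
   number of letters finishing within τ = t − t₀ is B ~ Binomial(6, 1 −
   e^{−vτ}).
3. **Capacity.** A per-trial capacity K is drawn from a six-point
   distribution over 1..6 (five free probabilities; P(K=6) is one minus
   their sum). The score — the number of correctly reported letters — is
   min(K, B).

The marginal score distribution integrates the conditional pmf over t₀ by
Gauss–Hermite quadrature (64 nodes by default; exact evaluation when
σ_t₀ = 0). The likelihood is over the *count* of correct reports, not
letter identities or positions. Erroneously reported letters are simulated
(see below) but never modelled: participants are instructed to refrain from
guessing, so the likelihood treats reports as containing no guesses.

Degenerate inputs: τ ≤ 0 gives a point mass at score 0; probabilities are
floored at 1e-300 before logs so the likelihood is finite everywhere; the
σ_t₀ = 0 limit of the ex-Gaussian single-item encoding CDF falls back to
the plain exponential race CDF. The second exponential term of the
ex-Gaussian CDF is evaluated in log space (via `log_ndtr`) to avoid
overflow when vσ² is large.

## Free parameters and bounds

| parameter | meaning | units | default bounds |
|---|---|---|---|
| μ_t₀ | mean threshold of conscious perception | ms | [0, 200] |
| σ_t₀ | across-trial SD of the threshold | ms | [0.01, 100] |
| C | total visual processing speed | letters/s | [1, 500] |
| p₁..p₅ | P(capacity = 1..5) | — | simplex |

The lower bound of 0.01 ms on σ_t₀ is a numerical stability choice, not a
substantive one. Fitting works in an unconstrained 8-vector: identity
(clipped) for μ_t₀, log for σ_t₀ and C (clipped in log space), and
stick-breaking log-odds for the capacity probabilities, so any real vector
maps to a valid parameter set and interior parameters round-trip to 1e-10.

The optimizer is L-BFGS-B on the negative log-likelihood with multi-start:
a moment-based initial guess (threshold from the shortest duration with
non-trivial mean score; C from the initial slope of mean score vs duration,
which is ≈ C/1000 per ms near threshold; capacity from the smoothed score
histogram at the two longest durations) plus seeded jittered copies
(8 starts by default). Ties between starts break toward the lowest start
index, so a fit is deterministic given data, config, and seed. A session in
which no letter was ever reported leaves C unidentified; it is returned
pinned at the lower bound and flagged.

## Synthetic cohort

The generator emulates a two-device, two-session reliability study:
44 participants, each completing on both devices two sessions of 9 blocks ×
18 trials (plus an 18-trial practice block that is excluded from fitting)
at six exposure durations, 27 trials per duration. The CRT design uses
{10, 20, 50, 80, 140, 200} ms; the head-mounted display runs at 75 Hz, so
the same targets are frame-quantized to multiples of 13.3 ms —
{13, 27, 53, 80, 147, 200} ms displayed, with ties between neighbouring
frame counts broken toward the longer duration (that tie-break is what maps
20 → 27 and 140 → 147). Simulation uses the exact frame multiples
(26.67 ms, …); the CSV carries both the target and the nominal duration.

Across participants, each component's (session-1, session-2) true values
are bivariate normal with a configurable test-retest correlation ρ, a
session shift (practice effect) added to the session-2 mean, and a device
offset added on the CRT. Defaults emulate the published descriptives:
thresholds ≈ 13 ms (SD 5) that drop ≈ 2.5 ms with practice, speeds ≈ 81
letters/s (SD 36) that rise with practice, capacities ≈ 3.7 letters
(SD 0.7), within-trial threshold SD 10 ms, and ρ defaults of 0.6/0.6/0.8.
The published speed practice effect differs by device (+32 letters/s on the
head-mounted display vs +6 on the CRT); the cohort spec deliberately keeps
one scalar shift per component and uses an intermediate default, since the
generator's role is structural emulation, not reproduction of any
particular sample. Draws outside the admissible ranges (e.g. negative
speeds) are rejected and redrawn, with redraw counts logged.

A scalar expected-capacity target maps to the six-point distribution as a
shifted binomial K = 1 + Binomial(5, (target−1)/5), a one-parameter family
whose mean is exactly the target — a full six-vector per participant would
not be identifiable from 162 trials anyway.

Reported letters are corrupted independently with probability 0.11 into a
random non-displayed letter, emulating the instructed 10–20% error band;
errors enter the error-rate descriptive but never the likelihood.

Randomness uses per-participant `SeedSequence` substreams, split again into
a truth stream and a trial stream, so (a) adding participants never
perturbs earlier ones and (b) the true-component table can be regenerated
without simulating trials (`simulate_cohort_truth`).

What the generator does **not** emulate: positional/letter confusability
effects, guessing, fatigue or within-session drift, device-specific
perceptual differences beyond additive component offsets, and report-mode
differences (typed vs verbal). Tests passing on this synthetic cohort show
that the estimator and statistics recover the structure the model assumes;
they cannot show that real observers satisfy those assumptions.

## Reliability statistics

Implemented exactly as the standard formulas: Pearson r with a two-sided
t-test on n−2 df; Fisher-z 95% CIs, tanh(atanh(r) ± 1.96/√(n−3)); Steiger's
Z for *independent* correlations, (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)) — the dependent-correlation variant is intentionally not used;
paired t with d_z = mean(d)/sd(d) = t/√n. The error rate is wrong letters
over reported letters; empty reports contribute no letters. The report is
complete-case: participants missing any device × session cell are dropped
with a logged warning. Display rounding follows the field's table dialect
(r and CI to 2 dp, p to 3 dp with "<0.001" below).

A note on recomputing published values from rounded inputs: CI bounds and
d_z recomputed from printed correlations and t statistics agree with
printed tables to 2 decimals in all but boundary cases (a printed r of 0.74
at n = 44 gives a lower CI bound of 0.568, which rounds one step below the
printed 0.58, and printed Steiger Z's differ in the third decimal), because
the original computations used unrounded inputs.

## Validation and problem sizes

The package validates itself four ways (all in `tests/` and
`scripts/acceptance.py`):

- **Dual-route model check**: the analytic score pmf against an explicit
  race simulation (10⁶ trials per condition, 20 random parameter sets,
  every bin within 3 binomial SEs), plus exact closed forms in the hard
  threshold / fixed-capacity limit (Binomial(6, 1−e^{−vτ})).
- **Parameter recovery**: 20 replicate single sessions at the study's
  design scale (162 trials, 6 durations) from μ_t₀ = 14 ms, σ_t₀ = 5 ms,
  C = 80 letters/s, E[K] = 3.9; median recovered C within ±20%, E[K] within
  ±0.4 letters, μ_t₀ within ±5 ms. Speed is the weakest-identified
  component at single-session volume — C trades off against σ_t₀ when the
  score curve saturates near capacity — which is also why its fitted
  test-retest correlation is attenuated relative to the generating ρ
  (classical attenuation, r_obs ≈ ρ·√(R₁R₂) with R the true-score variance
  ratio). The end-to-end cohort test checks the fitted correlations against
  that prediction; the Fisher-z sampling-bound check (within 4 SE of
  atanh ρ over 200 replicate 44-participant cohorts) runs on the error-free
  component tables where the bound is well defined.
- **Statistic calibration**: type-I error of the Steiger test 0.05 ± 0.01
  under an equal-ρ null (10,000 replicates, n = 44 per group), and of the
  correlation t-test likewise.
- **Published recomputables**: CI bounds, d_z identities, and the 75 Hz
  duration set, recomputed from printed inputs.

Problem sizes in the test suite (replicate counts, reduced 9-per-duration
sessions in the end-to-end fitted check, 4-start/32-node fit configs in
recovery studies) are chosen to keep the full validation cycle in the
few-minute range on one CPU while leaving every check's sampling error well
inside its tolerance.

## Known limitations

- Equal attentional weights only; no partial report, no per-position
  weights, no letter-confusion structure.
- No lapse/guessing parameter: a participant who guesses despite the
  instruction biases C upward.
- No standard errors or bootstrap CIs on fitted components.
- The independent-samples Steiger test ignores that the two device
  reliabilities come from the same participants; that is the analysis
  being emulated, not a recommendation.
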