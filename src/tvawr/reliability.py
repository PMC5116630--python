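"""Reliability statistics for the two-device, two-session component tables.

Implements the study-level analyses run on the fitted visual processing
components: descriptive statistics per device and session, Pearson
correlations between devices, test-retest correlations with Fisher-z
confidence intervals, Steiger's Z comparison of independent correlations,
and paired t-tests with Cohen's dz for session effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import TrialRecord

__all__ = [
    "COMPONENT_COLUMNS",
    "ReliabilityReport",
    "pearson_r",
    "fisher_ci",
    "steiger_z_independent",
    "paired_t",
    "error_rate",
    "build_report",
    "render_report",
]

#: Component columns of the per-participant table consumed by build_report.
COMPONENT_COLUMNS = ("t0_mean", "expected_K", "C", "error_rate")


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value
    on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("pearson_r needs two equal-length vectors with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pearson_r requires finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation: atanh(r) +/-
    z_crit / sqrt(n - 3), back-transformed with tanh."""
    if not abs(r) < 1:
        raise ValueError("fisher_ci requires |r| < 1")
    if n < 4:
        raise ValueError("fisher_ci requires n >= 4")
    z = np.arctanh(r)
    half = stats.norm.ppf((1.0 + level) / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def steiger_z_independent(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Steiger's Z-test comparing two correlations from independent samples.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("steiger_z_independent requires |r| < 1")
    if min(n1, n2) < 4:
        raise ValueError("steiger_z_independent requires n >= 4")
    Z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(Z))
    return float(Z), float(p)


def paired_t(x, y) -> tuple[float, int, float, float]:
    """Paired t-test with Cohen's dz effect size.

    Returns ``(t, df, p, dz)`` where ``dz = mean(d) / sd(d) = t / sqrt(n)``
    for the differences ``d = x - y`` and ``df = n - 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors with n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() != 0:
            raise ZeroDivisionError("paired_t: zero-variance differences with nonzero mean")
        return 0.0, n - 1, 1.0, 0.0
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    return t, n - 1, float(res.pvalue), t / np.sqrt(n)


def error_rate(trials: list[TrialRecord]) -> float:
    """Proportion of erroneously reported letters among all reported letters.

    An empty report contributes no letters, hence no errors; a session in
    which nothing was ever reported has no defined error rate.
    """
    n_reported = sum(len(t.reported_letters) for t in trials)
    if n_reported == 0:
        raise ValueError("error rate undefined: no letters reported")
    return sum(t.n_errors for t in trials) / n_reported


@dataclass(frozen=True)
class ReliabilityReport:
    """The study-level result tables.

    descriptives : mean and SD per device x session x component
    cross_device : Pearson r (and p) between devices, per session x component
    test_retest  : session-1 vs session-2 r with p and 95% Fisher CI,
                   per device x component
    steiger      : Z and p comparing the two devices' test-retest r,
                   per component
    paired_tests : session-1 vs session-2 paired t, df, p, dz,
                   per device x component
    """

    descriptives: pd.DataFrame
    cross_device: pd.DataFrame
    test_retest: pd.DataFrame
    steiger: pd.DataFrame
    paired_tests: pd.DataFrame
    n_participants: int
    excluded: tuple = ()


def _complete_cases(components: pd.DataFrame):
    required = {"participant_id", "device", "session", *COMPONENT_COLUMNS} - {"error_rate"}
    missing = required - set(components.columns)
    if missing:
        raise ValueError(f"component table missing columns: {sorted(missing)}")
    devices = sorted(components["device"].unique())
    sessions = sorted(components["session"].unique())
    n_cells = len(devices) * len(sessions)
    counts = components.groupby("participant_id").size()
    complete = counts[counts == n_cells].index
    excluded = tuple(sorted(set(components["participant_id"]) - set(complete)))
    if excluded:
        import logging

        logging.getLogger(__name__).warning(
            "build_report: dropping %d incomplete participants: %s", len(excluded), excluded
        )
    return components[components["participant_id"].isin(complete)], devices, sessions, excluded


def build_report(components: pd.DataFrame) -> ReliabilityReport:
    """Assemble every reliability statistic from a component table.

    ``components`` has one row per participant x device x session with the
    fitted components as columns.  Participants missing any of the four
    cells are dropped (complete-case analysis) with a logged warning.
    """
    data, devices, sessions, excluded = _complete_cases(components)
    desc_cols = [c for c in COMPONENT_COLUMNS if c in data.columns]
    # correlations and session tests cover the three model components only;
    # the error rate is descriptive (an instruction-compliance check)
    cols = [c for c in desc_cols if c != "error_rate"]
    wide = data.pivot_table(
        index="participant_id", columns=["device", "session"], values=list(desc_cols)
    )
    n = len(wide)

    desc_rows = []
    for dev in devices:
        for ses in sessions:
            for comp in desc_cols:
                vals = wide[(comp, dev, ses)]
                desc_rows.append(
                    {"device": dev, "session": ses, "component": comp,
                     "mean": vals.mean(), "sd": vals.std(ddof=1)}
                )
    descriptives = pd.DataFrame(desc_rows)

    cross_rows = []
    if len(devices) == 2:
        d1, d2 = devices
        for ses in sessions:
            for comp in cols:
                r, p = pearson_r(wide[(comp, d1, ses)], wide[(comp, d2, ses)])
                cross_rows.append({"session": ses, "component": comp, "r": r, "p": p})
    cross_device = pd.DataFrame(cross_rows)

    retest_rows = []
    for dev in devices:
        for comp in cols:
            r, p = pearson_r(wide[(comp, dev, 1)], wide[(comp, dev, 2)])
            lo, hi = fisher_ci(r, n) if abs(r) < 1 else (r, r)
            retest_rows.append(
                {"device": dev, "component": comp, "r": r, "p": p, "ci_low": lo, "ci_high": hi}
            )
    test_retest = pd.DataFrame(retest_rows)

    steiger_rows = []
    if len(devices) == 2:
        for comp in cols:
            rows = test_retest[test_retest["component"] == comp]
            r1 = rows[rows["device"] == devices[0]]["r"].iloc[0]
            r2 = rows[rows["device"] == devices[1]]["r"].iloc[0]
            if r1 == r2:
                Z, p = 0.0, 1.0  # covers the degenerate r1 = r2 = 1 case
            elif abs(r1) >= 1 or abs(r2) >= 1:
                Z, p = float("nan"), float("nan")
            else:
                Z, p = steiger_z_independent(r1, n, r2, n)
            steiger_rows.append({"component": comp, "Z": Z, "p": p})
    steiger = pd.DataFrame(steiger_rows)

    paired_rows = []
    for dev in devices:
        for comp in cols:
            t, df, p, dz = paired_t(wide[(comp, dev, 1)], wide[(comp, dev, 2)])
            paired_rows.append(
                {"device": dev, "component": comp, "t": t, "df": df, "p": p, "dz": dz}
            )
    paired_tests = pd.DataFrame(paired_rows)

    return ReliabilityReport(
        descriptives=descriptives, cross_device=cross_device, test_retest=test_retest,
        steiger=steiger, paired_tests=paired_tests, n_participants=n, excluded=excluded,
    )


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_report(report: ReliabilityReport) -> str:
    """Plain-text rendering with the tables' display conventions:
    r and CI bounds to 2 decimals, p to 3 decimals with '<0.001' below."""
    lines = [f"Reliability report (n = {report.n_participants} complete participants)"]
    if report.excluded:
        lines.append(f"Excluded (incomplete): {', '.join(report.excluded)}")
    lines.append("\nDescriptives: M (SD)")
    for _, row in report.descriptives.iterrows():
        lines.append(
            f"  {row['device']} session {row['session']} {row['component']}: "
            f"{row['mean']:.2f} ({row['sd']:.2f})"
        )
    if len(report.cross_device):
        lines.append("\nCross-device correlations: r (p)")
        for _, row in report.cross_device.iterrows():
            lines.append(
                f"  session {row['session']} {row['component']}: "
                f"{row['r']:.2f} ({_fmt_p(row['p'])})"
            )
    lines.append("\nTest-retest reliabilities: r (p) [95% CI]")
    for _, row in report.test_retest.iterrows():
        lines.append(
            f"  {row['device']} {row['component']}: {row['r']:.2f} ({_fmt_p(row['p'])}) "
            f"[{row['ci_low']:.2f}; {row['ci_high']:.2f}]"
        )
    if len(report.steiger):
        lines.append("\nSteiger's Z (device comparison of test-retest r)")
        for _, row in report.steiger.iterrows():
            lines.append(f"  {row['component']}: Z = {row['Z']:.3f}, p = {_fmt_p(row['p'])}")
    lines.append("\nSession effects: paired t (df), p, dz")
    for _, row in report.paired_tests.iterrows():
        lines.append(
            f"  {row['device']} {row['component']}: t({row['df']}) = {row['t']:.3f}, "
            f"p = {_fmt_p(row['p'])}, dz = {row['dz']:.2f}"
        )
    return "\n".join(lines)
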