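"""File formats: trial-level CSV, parameter JSON, component tables, config.

The trial CSV is the interchange format for whole-report data (one row per
trial); parameter files are JSON with units spelled out in the key names.
All readers validate explicitly and fail with named columns or line
numbers rather than silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import N_ITEMS, TVAParams, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "read_params_json",
    "write_params_json",
    "read_components",
    "write_components",
    "load_config",
]

TRIAL_COLUMNS = (
    "participant_id", "device", "session", "block", "trial_index",
    "exposure_target_ms", "exposure_nominal_ms", "n_displayed",
    "displayed_letters", "reported_letters", "n_correct", "n_errors",
)


class SchemaError(ValueError):
    """A file is structurally invalid (missing columns / keys)."""


def trials_to_frame(trials) -> pd.DataFrame:
    rows = [
        {
            "participant_id": t.participant_id,
            "device": t.device,
            "session": t.session,
            "block": t.block,
            "trial_index": t.trial_index,
            "exposure_target_ms": "" if t.exposure_target_ms is None else t.exposure_target_ms,
            "exposure_nominal_ms": t.exposure_ms,
            "n_displayed": t.n_displayed,
            "displayed_letters": t.displayed_letters,
            "reported_letters": t.reported_letters,
            "n_correct": t.n_correct,
            "n_errors": t.n_errors,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def write_trials(trials, path) -> None:
    """Write trial records to CSV (UTF-8, header row, full float precision)."""
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.17g")


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a trial CSV; raises with line numbers on bad rows."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "displayed_letters": str, "reported_letters": str},
        keep_default_na=False,
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial CSV missing required columns: {sorted(missing)}")
    trials = []
    errors = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            n_correct = int(row.n_correct)
            if not 0 <= n_correct <= N_ITEMS:
                raise ValueError(f"n_correct={n_correct} outside 0..{N_ITEMS}")
            target = row.exposure_target_ms
            trials.append(
                TrialRecord(
                    participant_id=str(row.participant_id),
                    device=str(row.device),
                    session=int(row.session),
                    block=int(row.block),
                    trial_index=int(row.trial_index),
                    exposure_ms=float(row.exposure_nominal_ms),
                    n_displayed=int(row.n_displayed),
                    displayed_letters=str(row.displayed_letters),
                    reported_letters=str(row.reported_letters),
                    n_correct=n_correct,
                    n_errors=int(row.n_errors),
                    exposure_target_ms=None if target in ("", None) else float(target),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise ValueError("invalid trial rows:\n" + "\n".join(errors[:20]))
    return trials


PARAM_KEYS = ("t0_mean_ms", "t0_sd_ms", "C_items_per_s", "k_probs")


def write_params_json(params: TVAParams, path, **provenance) -> None:
    """Write fitted parameters as JSON; extra keyword arguments (seed,
    n_trials, loglik, converged, ...) are stored under 'provenance'."""
    payload = {
        "t0_mean_ms": params.t0_mean,
        "t0_sd_ms": params.t0_sd,
        "C_items_per_s": params.C,
        "k_probs": [float(p) for p in params.k_probs],
    }
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params_json(path) -> TVAParams:
    payload = json.loads(Path(path).read_text())
    missing = set(PARAM_KEYS) - set(payload)
    if missing:
        raise SchemaError(f"params JSON missing keys: {sorted(missing)}")
    k = np.asarray(payload["k_probs"], dtype=float)
    return TVAParams(
        t0_mean=float(payload["t0_mean_ms"]),
        t0_sd=float(payload["t0_sd_ms"]),
        C=float(payload["C_items_per_s"]),
        k_probs=k,
    )


COMPONENT_CSV_COLUMNS = (
    "participant_id", "device", "session", "t0_mean", "t0_sd", "C", "expected_K", "error_rate",
)


def write_components(components: pd.DataFrame, path) -> None:
    components.to_csv(path, index=False, float_format="%.17g")


def read_components(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = {"participant_id", "device", "session", "t0_mean", "C", "expected_K"} - set(df.columns)
    if missing:
        raise SchemaError(f"components CSV missing columns: {sorted(missing)}")
    if not df["session"].isin([1, 2]).all():
        raise ValueError("components CSV: session must be 1 or 2")
    for col in df.columns:
        if col not in ("participant_id", "device", "session", "converged", "n_trials"):
            df[col] = df[col].astype(float)
    return df


def load_config(path) -> dict:
    """Load a YAML pipeline configuration (nested key/value sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping of sections")
    return cfg
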