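"""Canonical file formats: trial tables, configuration, run metadata.

The trial table is a comma-delimited UTF-8 file with a fixed, ordered
header.  Angles are degrees in the signed geometric convention and must
lie in (-180, 180]; values wrapped by a full turn are normalized with a
warning.  An empty cell means "not applicable" (e.g. no perturbation on
a veridical trial).
"""

from __future__ import annotations

import json
import warnings
from typing import Any, Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from premo.core import PremoParams
from premo.errors import ParameterError, TrialTableError

__all__ = [
    "TRIAL_TABLE_COLUMNS",
    "read_trial_table",
    "write_trial_table",
    "load_config",
    "write_run_metadata",
    "to_paper_signs",
]

TRIAL_TABLE_COLUMNS = [
    "subject_id",
    "trial",
    "block_label",
    "feedback_mode",
    "perturbation_deg",
    "movement_mode",
    "target_deg",
    "hand_angle_deg",
    "report_angle_deg",
    "probe_angle_deg",
    "probe_report_deg",
]

_ANGLE_COLUMNS = [
    "perturbation_deg",
    "target_deg",
    "hand_angle_deg",
    "report_angle_deg",
    "probe_angle_deg",
    "probe_report_deg",
]

CONFIG_SPEC_VERSION = "1"


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table with the canonical ordered header."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    extra = [c for c in table.columns if c not in TRIAL_TABLE_COLUMNS]
    table[TRIAL_TABLE_COLUMNS + extra].to_csv(path, index=False, encoding="utf-8")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table; lossless round-trip with write.

    Raises :class:`~premo.errors.TrialTableError` for missing required
    columns, non-numeric angles, duplicated (subject, trial) pairs, or a
    rotation/clamp trial without a perturbation.  Unknown columns are
    preserved with a warning.
    """
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    extra = [c for c in table.columns if c not in TRIAL_TABLE_COLUMNS]
    if extra:
        warnings.warn(f"unknown columns preserved: {extra}", stacklevel=2)

    for col in _ANGLE_COLUMNS:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna() & (table[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise TrialTableError(
                f"non-numeric angle in column {col!r}, row {row}: "
                f"{table.loc[row, col]!r}"
            )
        table[col] = values

    dup = table.duplicated(subset=["subject_id", "trial"])
    if dup.any():
        row = int(dup.idxmax())
        pair = (table.loc[row, "subject_id"], table.loc[row, "trial"])
        raise TrialTableError(f"duplicated (subject, trial) pair {pair} at row {row}")

    needs_pert = table["feedback_mode"].isin(["rotation", "clamp"])
    missing_pert = needs_pert & table["perturbation_deg"].isna()
    if missing_pert.any():
        row = int(missing_pert.idxmax())
        raise TrialTableError(
            f"{table.loc[row, 'feedback_mode']} trial at row {row} "
            "is missing perturbation_deg"
        )

    for col in _ANGLE_COLUMNS:
        vals = table[col]
        out_of_range = vals.notna() & ((vals <= -180.0) | (vals > 180.0))
        if out_of_range.any():
            warnings.warn(
                f"column {col!r}: {int(out_of_range.sum())} angle(s) outside "
                "(-180, 180] normalized by wrapping",
                stacklevel=2,
            )
            wrapped = -((-vals[out_of_range] + 180.0) % 360.0 - 180.0)
            table.loc[out_of_range, col] = wrapped
    return table


_PARAM_FIELDS = (
    "w_p", "w_v", "eta_p", "eta_v",
    "beta_p_sat", "beta_v_sat", "K", "A_ret",
)


def load_config(path) -> Tuple[PremoParams, Dict[str, Any], Dict[str, Any]]:
    """Load a flat key-value YAML config.

    Returns ``(params, schedule_descriptor, run_options)``.  Any model
    parameter not given takes the package default; variances
    (``sigma_u2``/``sigma_p2``/``sigma_v2``) may be given instead of
    weights, in which case the weights are derived from the reliability
    ratios.  Schedule keys are collected under ``schedule.*``; remaining
    keys become run options.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config must be a flat key-value mapping")
    version = str(raw.pop("spec_version", CONFIG_SPEC_VERSION))
    if version != CONFIG_SPEC_VERSION:
        raise ParameterError(f"unsupported config spec_version {version!r}")

    variances = {
        k: raw.pop(k) for k in ("sigma_u2", "sigma_p2", "sigma_v2") if k in raw
    }
    param_kwargs = {k: raw.pop(k) for k in _PARAM_FIELDS if k in raw}
    if "update_without_feedback" in raw:
        param_kwargs["update_without_feedback"] = bool(
            raw.pop("update_without_feedback")
        )
    try:
        if variances:
            if set(variances) != {"sigma_u2", "sigma_p2", "sigma_v2"}:
                raise ParameterError(
                    "give all three variances (sigma_u2, sigma_p2, sigma_v2) "
                    "or none"
                )
            for key in ("w_p", "w_v"):
                param_kwargs.pop(key, None)
            params = PremoParams.from_variances(**variances, **param_kwargs)
        else:
            params = PremoParams(**param_kwargs)
    except ParameterError:
        raise
    except (TypeError, ValueError) as exc:
        raise ParameterError(str(exc)) from exc

    schedule_desc = {
        k[len("schedule."):]: v for k, v in raw.items() if k.startswith("schedule.")
    }
    run_options = {
        k: v for k, v in raw.items() if not k.startswith("schedule.")
    }
    return params, schedule_desc, run_options


def write_run_metadata(path, *, command: str, params: PremoParams,
                       seed: int | None, options: Dict[str, Any] | None = None) -> None:
    """Record everything needed to reproduce a run bit-exactly."""
    from premo import __version__

    payload = {
        "command": command,
        "package_version": __version__,
        "spec_version": CONFIG_SPEC_VERSION,
        "seed": seed,
        "params": {f: getattr(params, f) for f in _PARAM_FIELDS},
        "update_without_feedback": params.update_without_feedback,
        "options": options or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def to_paper_signs(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a geometric-convention table to reporting conventions.

    Adaptation is reported positive (away from the perturbation) and
    report/probe angles keep their sign relative to the flipped axis.
    Rows without a perturbation use the schedule's dominant perturbation
    sign so baseline and washout trials stay on a consistent axis.
    """
    out = table.copy()
    pert = out["perturbation_deg"]
    nonzero = pert.dropna()
    nonzero = nonzero[nonzero != 0]
    default_sign = float(np.sign(nonzero.iloc[0])) if len(nonzero) else 1.0
    sign = np.where(pert.notna() & (pert != 0), np.sign(pert), default_sign)
    for col in ("hand_angle_deg", "report_angle_deg", "probe_report_deg"):
        out[col] = -sign * out[col]
    return out
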