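"""Synthetic multi-subject trial tables with the model's noise structure.

Noise enters in three places, mirroring how the corresponding behavioural
measures are collected:

* motor noise — execution noise added to each active reach.  The noisy
  executed angle is what the senses register, so it enters the trial's
  integration/recalibration cascade, deflects the cursor on
  movement-contingent trials (veridical, rotation; clamp cursors are
  fixed by design), and thereby feeds the error that updates the next
  trial's state.  The learned state itself evolves from the planned
  angle: execution noise is not stored in the sensorimotor map;
* report noise — added to verbal reports of felt hand position;
* probe noise — added to passive localization probe reports.

Subject heterogeneity draws each parameter from a Gaussian centred on
the group value, truncated to the parameter's valid range by rejection
sampling.  Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from premo.core import ModelState, PremoParams, step_trial
from premo.errors import ParameterError
from premo.io import TRIAL_TABLE_COLUMNS
from premo.paradigms import Schedule

__all__ = ["generate_dataset", "draw_subject_params"]

# open/closed bounds used for truncated parameter draws
_PARAM_RANGES: Dict[str, tuple] = {
    "w_p": (1e-9, 1.0),
    "w_v": (1e-9, 1.0),
    "eta_p": (0.0, 1.0 - 1e-9),
    "eta_v": (0.0, 1.0 - 1e-9),
    "beta_p_sat": (0.0, np.inf),
    "beta_v_sat": (0.0, np.inf),
    "K": (0.0, 1.0),
    "A_ret": (0.0, 1.0),
}
_MAX_DRAWS = 1000


def draw_subject_params(
    params: PremoParams,
    heterogeneity: Mapping[str, float],
    rng: np.random.Generator,
) -> PremoParams:
    """One subject's parameters: truncated-Gaussian perturbation of the
    group-level values."""
    updates: Dict[str, float] = {}
    for name, sd in heterogeneity.items():
        if name not in _PARAM_RANGES:
            raise ParameterError(f"unknown parameter {name!r} in heterogeneity")
        if sd < 0:
            raise ParameterError(f"heterogeneity sd for {name!r} must be >= 0")
        lo, hi = _PARAM_RANGES[name]
        mean = getattr(params, name)
        if not lo <= mean <= hi:
            raise ParameterError(
                f"group value {name}={mean} outside truncation range [{lo}, {hi}]"
            )
        if sd == 0:
            continue
        for _ in range(_MAX_DRAWS):
            value = rng.normal(mean, sd)
            if lo <= value <= hi:
                updates[name] = float(value)
                break
        else:
            raise ParameterError(
                f"could not draw {name} within [{lo}, {hi}] "
                f"(mean {mean}, sd {sd})"
            )
    return replace(params, **updates) if updates else params


def generate_dataset(
    params: PremoParams,
    schedule: Schedule,
    motor_noise_sd: float = 0.0,
    report_noise_sd: float = 0.0,
    probe_noise_sd: float = 0.0,
    subject_heterogeneity: Optional[Mapping[str, float]] = None,
    n_subjects: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate noisy subjects over a schedule; canonical trial table out.

    With all noise SDs and heterogeneity zero the table equals the
    noise-free simulation exactly.
    """
    for name, sd in (
        ("motor_noise_sd", motor_noise_sd),
        ("report_noise_sd", report_noise_sd),
        ("probe_noise_sd", probe_noise_sd),
    ):
        if sd < 0:
            raise ParameterError(f"{name} must be >= 0")
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    heterogeneity = dict(subject_heterogeneity or {})
    rng = np.random.default_rng(seed)

    rows = []
    for subj in range(n_subjects):
        subj_params = draw_subject_params(params, heterogeneity, rng)
        state = ModelState()
        for i, spec in enumerate(schedule):
            noise = 0.0
            if spec.movement_mode == "active" and motor_noise_sd:
                noise = rng.normal(0.0, motor_noise_sd)
            # the senses (and contingent cursor) see the noisy executed
            # reach; the map update applies on top of the planned angle
            state, rec = step_trial(
                replace(state, x_p=state.x_p + noise), spec, subj_params
            )
            state = replace(state, x_p=state.x_p - noise)

            report = np.nan
            if "hand_report" in spec.probes:
                report = rec.perceived_hand + (
                    rng.normal(0.0, report_noise_sd) if report_noise_sd else 0.0
                )
            probe = np.nan
            probe_angle = np.nan
            if "passive_probe" in spec.probes:
                probe_angle = spec.probe_angle_deg
                probe = (
                    spec.probe_angle_deg
                    + rec.beta_p
                    + (rng.normal(0.0, probe_noise_sd) if probe_noise_sd else 0.0)
                )
            rows.append(
                {
                    "subject_id": f"S{subj + 1:03d}",
                    "trial": i,
                    "block_label": spec.block_label,
                    "feedback_mode": spec.feedback_mode,
                    "perturbation_deg": (
                        np.nan
                        if spec.perturbation_deg is None
                        else spec.perturbation_deg
                    ),
                    "movement_mode": spec.movement_mode,
                    "target_deg": spec.target_deg,
                    "hand_angle_deg": rec.hand_angle,
                    "report_angle_deg": report,
                    "probe_angle_deg": probe_angle,
                    "probe_report_deg": probe,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
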