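"""Visuo-centric state-space model of adaptation, as a reference learner.

Trial-to-trial learning driven by the visual error e (cursor minus
target): ``x[t+1] = A*x[t] + K*e[t]``, with retention A and learning rate
K.  Its asymptote is the learning/forgetting equilibrium ``K*e/(1-A)``
and therefore scales with error size — the central qualitative contrast
with the saturating proprioceptive re-alignment account.

``baseline_step`` and ``baseline_asymptote`` are the literal forms, with
x measured positive in the direction of compensation (the convention in
which learning curves are plotted).  ``simulate_baseline`` runs in the
package's signed geometric convention (counterclockwise positive), where
compensation opposes the error, i.e. ``x[t+1] = A*x[t] - K*e_geo[t]``;
the two differ only by the sign flip between conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import pandas as pd

from premo.errors import ParameterError, RegimeError
from premo.paradigms import Schedule

__all__ = [
    "BaselineParams",
    "baseline_step",
    "baseline_asymptote",
    "simulate_baseline",
]


@dataclass(frozen=True)
class BaselineParams:
    """Retention A and learning rate K of the visuo-centric learner."""

    A: float = 0.9
    K: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.A <= 1.0:
            raise ParameterError(f"A must be in [0, 1], got {self.A}")
        if not 0.0 <= self.K <= 1.0:
            raise ParameterError(f"K must be in [0, 1], got {self.K}")


def baseline_step(x_t: float, e_t: float, params: BaselineParams) -> float:
    """One trial of the state-space learner: ``A*x + K*e``."""
    return params.A * x_t + params.K * e_t


def baseline_asymptote(e: float, params: BaselineParams) -> float:
    """Equilibrium extent ``K*e/(1-A)`` under a constant visual error."""
    if params.A >= 1.0:
        if e == 0.0:
            return 0.0
        raise RegimeError("A=1 with nonzero error has no equilibrium")
    return params.K * e / (1.0 - params.A)


def _visual_error(spec, x: float) -> float:
    if spec.feedback_mode == "clamp":
        # cursor fixed at the clamp angle regardless of the hand
        return spec.perturbation_deg - spec.target_deg
    if spec.feedback_mode == "rotation":
        return (x + spec.perturbation_deg) - spec.target_deg
    if spec.feedback_mode == "veridical":
        return x - spec.target_deg
    return 0.0  # no feedback: retention only


def simulate_baseline(
    schedule: Schedule,
    params: BaselineParams,
    x0: float = 0.0,
) -> pd.DataFrame:
    """Run the learner over a schedule; returns trial, hand angle, error.

    Hand angle is in the geometric convention (a +15 deg clamp drives it
    negative); compensation therefore opposes the signed visual error.
    """
    x = x0
    rows: List[dict] = []
    for i, spec in enumerate(schedule):
        e = _visual_error(spec, x)
        rows.append(
            {
                "trial": i,
                "block_label": spec.block_label,
                "hand_angle": x,
                "visual_error": e,
                "model_name": "baseline",
            }
        )
        x = baseline_step(x, -e, params)
    return pd.DataFrame(
        rows, columns=["trial", "block_label", "hand_angle", "visual_error", "model_name"]
    )
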