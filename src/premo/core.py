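"""Single-trial dynamics of the proprioceptive re-alignment model (PReMo).

The model treats implicit motor adaptation as the nulling of a
*proprioceptive* error: the mismatch between where the hand is perceived
to be and where the movement goal is perceived to be.  Perceived hand
position is built in two stages:

1. *Intramodal integration* — the afferent signal from each modality is
   averaged with the sensory expectation derived from the outgoing motor
   command (efference copy).  The weights ``w_p`` and ``w_v`` are the
   reliability ratios ``sigma_u^2 / (sigma_u^2 + sigma_p^2)`` and
   ``sigma_u^2 / (sigma_u^2 + sigma_v^2)``, where ``sigma_u^2`` is the
   variance of the efference-based prediction and ``sigma_p^2`` /
   ``sigma_v^2`` are proprioceptive / visual afferent variances.
2. *Crossmodal recalibration* — the integrated hand estimate is attracted
   toward the integrated cursor estimate (proprioceptive shift ``beta_p``)
   and vice versa (visual shift ``beta_v``).  Each shift is a fixed ratio
   (``eta_p``, ``eta_v``) of the intersensory discrepancy for small
   discrepancies and saturates at ``beta_p_sat`` / ``beta_v_sat`` for
   large ones.

The visual shift is global: it displaces the remembered target exactly as
it displaces the cursor, so the error that drives learning is
``perceived target - perceived hand``.  The sensorimotor map is updated by
a fraction ``K`` of that error; during no-feedback trials both shifts
decay by the retention factor ``A_ret``.

All angles are in degrees in a single geometric convention: measured
relative to the target direction (target = 0 deg), counterclockwise
positive.  Adaptation to a +c clamp therefore drives the hand angle
negative.  The sign bookkeeping used in behavioural reports (shift toward
the other modality negative, adaptation extent positive) is applied only
at the reporting layer, never inside the state update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional, Tuple

from premo.errors import ParameterError, ScheduleError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from premo.paradigms import TrialSpec

__all__ = [
    "PremoParams",
    "ModelState",
    "TrialRecord",
    "integrate_hand",
    "integrate_cursor",
    "crossmodal_shifts",
    "perceived_positions",
    "proprioceptive_error",
    "update_state",
    "decay_shifts",
    "step_trial",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class PremoParams:
    """Constants of the proprioceptive re-alignment model.

    Parameters
    ----------
    w_p, w_v
        Intramodal integration weights for proprioception and vision,
        in (0, 1].  A weight of 1 means the afferent signal is noiseless
        relative to the efference-based prediction.
    eta_p, eta_v
        Crossmodal recalibration ratios in [0, 1): fraction of the
        integrated visuo-proprioceptive discrepancy converted into a
        shift, below saturation.
    beta_p_sat, beta_v_sat
        Saturation magnitudes (deg) of the proprioceptive and visual
        shifts.  Empirically ~5 deg and ~1 deg.
    K
        Learning rate in [0, 1] applied to the proprioceptive error.
    A_ret
        Retention factor in [0, 1] applied to both shifts on trials
        without visual feedback.
    sigma_u2, sigma_p2, sigma_v2
        Optional variances (deg^2).  When provided they must be
        consistent with ``w_p`` and ``w_v``; use :meth:`from_variances`
        to derive the weights instead of supplying both.
    update_without_feedback
        Whether the sensorimotor map keeps updating from the (decaying)
        proprioceptive error on no-feedback trials.  Proprioception is
        available without vision, so this defaults to True; set False to
        freeze the map whenever the cursor is absent.
    """

    w_p: float = 0.25
    w_v: float = 0.9
    eta_p: float = 0.4
    eta_v: float = 0.1
    beta_p_sat: float = 5.0
    beta_v_sat: float = 1.0
    K: float = 0.2
    A_ret: float = 0.95
    sigma_u2: Optional[float] = None
    sigma_p2: Optional[float] = None
    sigma_v2: Optional[float] = None
    update_without_feedback: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.w_p <= 1.0:
            raise ParameterError(f"w_p must be in (0, 1], got {self.w_p}")
        if not 0.0 < self.w_v <= 1.0:
            raise ParameterError(f"w_v must be in (0, 1], got {self.w_v}")
        if not 0.0 <= self.eta_p < 1.0:
            raise ParameterError(f"eta_p must be in [0, 1), got {self.eta_p}")
        if not 0.0 <= self.eta_v < 1.0:
            raise ParameterError(f"eta_v must be in [0, 1), got {self.eta_v}")
        if self.beta_p_sat < 0.0:
            raise ParameterError(f"beta_p_sat must be >= 0, got {self.beta_p_sat}")
        if self.beta_v_sat < 0.0:
            raise ParameterError(f"beta_v_sat must be >= 0, got {self.beta_v_sat}")
        if not 0.0 <= self.K <= 1.0:
            raise ParameterError(f"K must be in [0, 1], got {self.K}")
        if not 0.0 <= self.A_ret <= 1.0:
            raise ParameterError(f"A_ret must be in [0, 1], got {self.A_ret}")
        if self.sigma_u2 is not None and self.sigma_p2 is not None:
            implied = self.sigma_u2 / (self.sigma_u2 + self.sigma_p2)
            if abs(implied - self.w_p) > _WEIGHT_TOL:
                raise ParameterError(
                    f"w_p={self.w_p} inconsistent with variances "
                    f"(sigma_u2={self.sigma_u2}, sigma_p2={self.sigma_p2} "
                    f"imply {implied})"
                )
        if self.sigma_u2 is not None and self.sigma_v2 is not None:
            implied = self.sigma_u2 / (self.sigma_u2 + self.sigma_v2)
            if abs(implied - self.w_v) > _WEIGHT_TOL:
                raise ParameterError(
                    f"w_v={self.w_v} inconsistent with variances "
                    f"(sigma_u2={self.sigma_u2}, sigma_v2={self.sigma_v2} "
                    f"imply {implied})"
                )

    @classmethod
    def from_variances(
        cls, sigma_u2: float, sigma_p2: float, sigma_v2: float, **kwargs: object
    ) -> "PremoParams":
        """Build parameters with weights derived from sensory variances."""
        if sigma_u2 <= 0 or sigma_p2 < 0 or sigma_v2 < 0:
            raise ParameterError(
                "variances must be positive (sigma_u2) / non-negative"
            )
        return cls(
            w_p=sigma_u2 / (sigma_u2 + sigma_p2),
            w_v=sigma_u2 / (sigma_u2 + sigma_v2),
            sigma_u2=sigma_u2,
            sigma_p2=sigma_p2,
            sigma_v2=sigma_v2,
            **kwargs,  # type: ignore[arg-type]
        )


@dataclass(frozen=True)
class ModelState:
    """Evolving latent state: hand angle and current sensory shifts."""

    x_p: float = 0.0
    beta_p: float = 0.0
    beta_v: float = 0.0
    trial_index: int = 0


@dataclass(frozen=True)
class TrialRecord:
    """Ledger of every model quantity computed on one trial.

    ``hand_angle`` is the hand angle executed on this trial (the state
    *before* the update); the post-update angle appears as the next
    trial's ``hand_angle``.  ``cursor_deg``, ``x_v_int`` and
    ``perceived_cursor`` are None on trials without visual feedback.
    ``probe_report`` is filled by the schedule runner on trials carrying
    a passive localization probe.
    """

    trial_index: int
    target_deg: float
    cursor_deg: Optional[float]
    x_p_int: float
    x_v_int: Optional[float]
    perceived_hand: float
    perceived_cursor: Optional[float]
    perceived_target: float
    prop_error: float
    update: float
    beta_p: float
    beta_v: float
    hand_angle: float
    probe_report: Optional[float] = None


def integrate_hand(hand_deg: float, goal_deg: float, w_p: float) -> float:
    """Intramodal integrated hand position.

    Weighted average of the afferent hand angle and the efference-based
    expectation (the movement goal): ``w_p * hand + (1 - w_p) * goal``.
    """
    if not 0.0 < w_p <= 1.0:
        raise ParameterError(f"w_p must be in (0, 1], got {w_p}")
    return w_p * hand_deg + (1.0 - w_p) * goal_deg


def integrate_cursor(cursor_deg: float, goal_deg: float, w_v: float) -> float:
    """Intramodal integrated cursor position: ``w_v*cursor + (1-w_v)*goal``."""
    if not 0.0 < w_v <= 1.0:
        raise ParameterError(f"w_v must be in (0, 1], got {w_v}")
    return w_v * cursor_deg + (1.0 - w_v) * goal_deg


def crossmodal_shifts(
    x_p_int: float, x_v_int: float, params: PremoParams
) -> Tuple[float, float]:
    """Saturating crossmodal recalibration of both modalities.

    Let ``delta = x_v_int - x_p_int`` be the integrated discrepancy.  The
    proprioceptive estimate shifts toward the cursor by
    ``min(eta_p*|delta|, beta_p_sat)`` and the visual estimate shifts
    toward the hand by ``min(eta_v*|delta|, beta_v_sat)``.  Returned as
    signed geometric displacements (``beta_p`` carries the sign of
    ``delta``, ``beta_v`` the opposite sign).
    """
    delta = x_v_int - x_p_int
    if delta == 0.0:
        return 0.0, 0.0
    s = math.copysign(1.0, delta)
    beta_p = s * min(params.eta_p * abs(delta), params.beta_p_sat)
    beta_v = -s * min(params.eta_v * abs(delta), params.beta_v_sat)
    return beta_p, beta_v


def perceived_positions(
    x_p_int: float,
    x_v_int: Optional[float],
    beta_p: float,
    beta_v: float,
    target_deg: float,
) -> Tuple[float, Optional[float], float]:
    """Perceived hand, cursor and target after crossmodal recalibration.

    The visual shift is global, so the remembered target is displaced by
    ``beta_v`` exactly like the cursor.
    """
    perceived_hand = x_p_int + beta_p
    perceived_cursor = None if x_v_int is None else x_v_int + beta_v
    perceived_target = target_deg + beta_v
    return perceived_hand, perceived_cursor, perceived_target


def proprioceptive_error(perceived_target: float, perceived_hand: float) -> float:
    """Driving error of adaptation: perceived target minus perceived hand."""
    return perceived_target - perceived_hand


def update_state(
    state: ModelState,
    error: float,
    K: float,
    has_visual_feedback: bool = True,
) -> ModelState:
    """Advance the sensorimotor map by ``K * error``; shifts carried as-is."""
    if not 0.0 <= K <= 1.0:
        raise ParameterError(f"K must be in [0, 1], got {K}")
    return replace(state, x_p=state.x_p + K * error)


def decay_shifts(beta_p: float, beta_v: float, A_ret: float) -> Tuple[float, float]:
    """Multiplicative decay of both shifts during feedback-free trials."""
    if not 0.0 <= A_ret <= 1.0:
        raise ParameterError(f"A_ret must be in [0, 1], got {A_ret}")
    return A_ret * beta_p, A_ret * beta_v


def _cursor_angle(spec: "TrialSpec", hand_deg: float) -> Optional[float]:
    mode = spec.feedback_mode
    if mode == "veridical":
        return hand_deg
    if mode == "rotation":
        return hand_deg + spec.perturbation_deg
    if mode == "clamp":
        return spec.perturbation_deg
    return None  # feedback_mode == "none"


def step_trial(
    state: ModelState, spec: "TrialSpec", params: PremoParams
) -> Tuple[ModelState, TrialRecord]:
    """One trial of the model: integration, recalibration, error, update.

    Active trials run the full cascade; the cursor is derived from the
    feedback mode (veridical: cursor = hand; rotation r: hand + r; clamp
    c: fixed at c; none: absent).  On no-feedback trials the shifts decay
    by ``A_ret`` and, by default, the map still updates from the residual
    proprioceptive error.  Passive trials reposition the hand without a
    motor command: integration weights are effectively 1 (integrated =
    actual positions), the shifts recalibrate, but no map update occurs
    and the planned reach direction is left untouched.
    """
    goal = spec.target_deg

    if spec.movement_mode == "passive":
        if spec.passive_hand_deg is None:
            raise ScheduleError(
                f"trial {state.trial_index}: passive trial lacks passive_hand_deg"
            )
        hand = spec.passive_hand_deg
        cursor = _cursor_angle(spec, hand)
        # No efference copy: integrated estimates equal the actual positions.
        x_p_int = hand
        if cursor is not None:
            x_v_int: Optional[float] = cursor
            beta_p, beta_v = crossmodal_shifts(x_p_int, x_v_int, params)
        else:
            x_v_int = None
            beta_p, beta_v = decay_shifts(state.beta_p, state.beta_v, params.A_ret)
        p_hand, p_cursor, p_target = perceived_positions(
            x_p_int, x_v_int, beta_p, beta_v, goal
        )
        error = proprioceptive_error(p_target, p_hand)
        new_state = ModelState(
            x_p=state.x_p,  # no motor command, no map update
            beta_p=beta_p,
            beta_v=beta_v,
            trial_index=state.trial_index + 1,
        )
        record = TrialRecord(
            trial_index=state.trial_index,
            target_deg=goal,
            cursor_deg=cursor,
            x_p_int=x_p_int,
            x_v_int=x_v_int,
            perceived_hand=p_hand,
            perceived_cursor=p_cursor,
            perceived_target=p_target,
            prop_error=error,
            update=0.0,
            beta_p=beta_p,
            beta_v=beta_v,
            hand_angle=hand,
        )
        return new_state, record

    hand = state.x_p
    cursor = _cursor_angle(spec, hand)
    x_p_int = integrate_hand(hand, goal, params.w_p)
    if cursor is not None:
        x_v_int = integrate_cursor(cursor, goal, params.w_v)
        beta_p, beta_v = crossmodal_shifts(x_p_int, x_v_int, params)
    else:
        x_v_int = None
        beta_p, beta_v = decay_shifts(state.beta_p, state.beta_v, params.A_ret)

    p_hand, p_cursor, p_target = perceived_positions(
        x_p_int, x_v_int, beta_p, beta_v, goal
    )
    error = proprioceptive_error(p_target, p_hand)

    if cursor is not None or params.update_without_feedback:
        increment = params.K * error
    else:
        increment = 0.0

    new_state = ModelState(
        x_p=hand + increment,
        beta_p=beta_p,
        beta_v=beta_v,
        trial_index=state.trial_index + 1,
    )
    record = TrialRecord(
        trial_index=state.trial_index,
        target_deg=goal,
        cursor_deg=cursor,
        x_p_int=x_p_int,
        x_v_int=x_v_int,
        perceived_hand=p_hand,
        perceived_cursor=p_cursor,
        perceived_target=p_target,
        prop_error=error,
        update=increment,
        beta_p=beta_p,
        beta_v=beta_v,
        hand_angle=hand,
    )
    return new_state, record
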