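"""Closed-form predictions of the proprioceptive re-alignment model.

All bounds are returned as magnitudes; under the geometric convention
the adapted hand angle lies on the opposite side of the target from the
perturbation, i.e. its sign is ``-sign(clamp_deg)``.

Saturated regime (large discrepancies, shifts pinned at their ceilings):
the hand stops moving when the perceived hand coincides with the
perceived target, which gives

    |x_UB| = (beta_p_sat + beta_v_sat) / w_p

With the visual shift disabled and ``w_p = sigma_u^2/(sigma_u^2 +
sigma_p^2)`` this is the familiar ``beta_p_sat * (1 + sigma_p^2 /
sigma_u^2)``: adaptation extent grows with proprioceptive uncertainty
and shrinks with prediction noise, independent of the error size.

Unsaturated regime (small clamps): the proprioceptive shift is
``eta_p * (w_v*c - w_p*x)``, and with visual shifts negligible the
equilibrium ``perceived hand = target`` solves to

    |x_UB| = eta_p * w_v * |c| / ((1 - eta_p) * w_p)

which now scales with the clamp size c and decreases as visual
uncertainty rises (lower w_v) — the uncertainty interaction that
disappears above saturation.
"""

from __future__ import annotations

import math

from premo.errors import ParameterError, RegimeError

__all__ = [
    "upper_bound_saturated",
    "upper_bound_unsaturated",
    "saturation_threshold",
    "adaptation_direction",
]


def adaptation_direction(perturbation_deg: float) -> float:
    """Sign of the adapted hand angle in the geometric convention."""
    if perturbation_deg == 0.0:
        return 0.0
    return -math.copysign(1.0, perturbation_deg)


def upper_bound_saturated(
    beta_p_sat: float, w_p: float, beta_v_sat: float = 0.0
) -> float:
    """Asymptotic adaptation magnitude when both shifts are saturated."""
    if w_p <= 0.0:
        raise ParameterError("w_p must be > 0 for a finite upper bound")
    if beta_p_sat < 0.0 or beta_v_sat < 0.0:
        raise ParameterError("saturation magnitudes must be >= 0")
    return (beta_p_sat + beta_v_sat) / w_p


def upper_bound_unsaturated(
    eta_p: float,
    w_p: float,
    w_v: float,
    clamp_deg: float,
    beta_p_sat: float | None = None,
) -> float:
    """Equilibrium adaptation magnitude for a clamp below saturation.

    Solves ``(1 - eta_p) * w_p * x = -eta_p * w_v * c`` (visual shift
    neglected, as appropriate for small discrepancies).  If
    ``beta_p_sat`` is supplied, the shift implied at equilibrium,
    ``eta_p * w_v * |c| / (1 - eta_p)``, is checked against it and a
    :class:`~premo.errors.RegimeError` directs the caller to the
    saturated bound when the regime assumption fails.
    """
    if not 0.0 <= eta_p < 1.0:
        raise ParameterError(f"eta_p must be in [0, 1), got {eta_p}")
    if w_p <= 0.0 or w_v <= 0.0:
        raise ParameterError("w_p and w_v must be > 0")
    implied_shift = eta_p * w_v * abs(clamp_deg) / (1.0 - eta_p)
    if beta_p_sat is not None and implied_shift >= beta_p_sat:
        raise RegimeError(
            f"implied shift {implied_shift:.3f} deg reaches saturation "
            f"({beta_p_sat} deg); use upper_bound_saturated"
        )
    return implied_shift / w_p


def saturation_threshold(eta_p: float, w_v: float, beta_p_sat: float) -> float:
    """Smallest clamp whose first-trial shift reaches the ceiling.

    On the first perturbed trial the hand is at the target, so the
    integrated discrepancy is ``w_v * c`` and the shift saturates once
    ``eta_p * w_v * c >= beta_p_sat``, i.e. at ``c* = beta_p_sat /
    (eta_p * w_v)``.
    """
    if eta_p <= 0.0:
        raise ParameterError("eta_p must be > 0 (threshold is infinite at 0)")
    if w_v <= 0.0:
        raise ParameterError("w_v must be > 0")
    if beta_p_sat < 0.0:
        raise ParameterError("beta_p_sat must be >= 0")
    return beta_p_sat / (eta_p * w_v)
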