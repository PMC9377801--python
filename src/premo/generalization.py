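"""Generalization of adaptation across reach directions.

Two components combine:

* a *far* (global) component — the enduring proprioceptive shift also
  biases the felt hand position at the start of the reach, so every
  movement is planned from a displaced start point toward the true
  target.  Executing that plan from the actual start deviates the
  heading everywhere in the workspace, with zero deviation along the
  shift axis and opposite rotation sense on either side of it;
* a *local* component — conventional direction-tuned transfer of the
  adapted state, modelled as a Gaussian kernel around the trained
  direction.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np

from premo.errors import ParameterError

__all__ = [
    "far_generalization",
    "local_generalization",
    "generalization_pattern",
    "wrap_angle",
]


def wrap_angle(deg):
    """Wrap angles into (-180, 180]."""
    wrapped = np.asarray(-((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0))
    return wrapped if wrapped.ndim else float(wrapped)


def far_generalization(
    probe_dirs: Iterable[float],
    start_shift_vec: Sequence[float],
    reach_amplitude: float,
) -> List[float]:
    """Heading deviations caused by a shifted perceived start position.

    For a probe target at distance ``reach_amplitude`` in direction
    ``theta`` the movement is planned from the perceived start
    (``start_shift_vec``, workspace units) to the target; the executed
    heading is the direction of that planned vector, and the deviation
    is ``executed heading - theta`` wrapped to (-180, 180].
    """
    if reach_amplitude <= 0:
        raise ParameterError("reach_amplitude must be > 0")
    shift = np.asarray(start_shift_vec, dtype=float)
    if shift.shape != (2,):
        raise ParameterError("start_shift_vec must be a 2-vector")
    theta = np.deg2rad(np.asarray(list(probe_dirs), dtype=float))
    targets = reach_amplitude * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    planned = targets - shift
    if np.any(np.linalg.norm(planned, axis=-1) == 0):
        raise ParameterError("perceived start coincides with a probe target")
    heading = np.rad2deg(np.arctan2(planned[:, 1], planned[:, 0]))
    return list(np.atleast_1d(wrap_angle(heading - np.rad2deg(theta))))


def local_generalization(
    adapted_deg: float,
    train_dir: float,
    probe_dirs: Iterable[float],
    kernel_width: float = 30.0,
) -> List[float]:
    """Gaussian-tuned transfer of the adapted state around ``train_dir``.

    ``kernel_width`` is the Gaussian SD in degrees of angular distance.
    """
    if kernel_width <= 0:
        raise ParameterError("kernel_width must be > 0")
    dist = np.abs(wrap_angle(np.asarray(list(probe_dirs), dtype=float) - train_dir))
    return list(adapted_deg * np.exp(-(dist**2) / (2.0 * kernel_width**2)))


def generalization_pattern(
    adapted_deg: float,
    train_dir: float,
    probe_dirs: Sequence[float],
    start_shift_vec: Sequence[float],
    reach_amplitude: float,
    kernel_width: float = 30.0,
) -> List[float]:
    """Total predicted deviation: local tuning plus the global start-shift
    component."""
    local = local_generalization(adapted_deg, train_dir, probe_dirs, kernel_width)
    far = far_generalization(probe_dirs, start_shift_vec, reach_amplitude)
    return [l + f for l, f in zip(local, far)]
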