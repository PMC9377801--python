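"""Trial schedules for the standard adaptation paradigms and a runner.

Builders cover the designs commonly used to probe implicit adaptation:
error-clamp blocks, abrupt or gradual visuomotor rotations with a
no-feedback aftereffect phase, and passive-exposure blocks in which a
robot displaces the hand while the cursor stays clamped at the target.
Schedules concatenate with ``+`` so multi-phase designs are composed from
the primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from premo.core import ModelState, PremoParams, TrialRecord, step_trial
from premo.errors import ScheduleError

__all__ = [
    "TrialSpec",
    "Schedule",
    "make_clamp_design",
    "make_rotation_design",
    "make_passive_exposure_design",
    "run_schedule",
]

FEEDBACK_MODES = ("veridical", "rotation", "clamp", "none")
MOVEMENT_MODES = ("active", "passive")
PROBE_KINDS = ("hand_report", "passive_probe")


@dataclass(frozen=True)
class TrialSpec:
    """Design of a single trial.

    ``perturbation_deg`` is the rotation size r (feedback_mode
    "rotation") or the clamp angle c ("clamp").  ``passive_hand_deg``
    gives the robot-imposed hand angle on passive trials.  ``probes``
    marks measurements taken on the trial: "hand_report" for a verbal
    report of felt hand position, "passive_probe" for a passive
    localization probe at ``probe_angle_deg``.
    """

    feedback_mode: str
    perturbation_deg: Optional[float] = None
    movement_mode: str = "active"
    passive_hand_deg: Optional[float] = None
    target_deg: float = 0.0
    probes: frozenset = frozenset()
    probe_angle_deg: float = 0.0
    block_label: str = ""

    def __post_init__(self) -> None:
        if self.feedback_mode not in FEEDBACK_MODES:
            raise ScheduleError(f"unknown feedback_mode {self.feedback_mode!r}")
        if self.movement_mode not in MOVEMENT_MODES:
            raise ScheduleError(f"unknown movement_mode {self.movement_mode!r}")
        needs_pert = self.feedback_mode in ("rotation", "clamp")
        if needs_pert and self.perturbation_deg is None:
            raise ScheduleError(
                f"{self.feedback_mode} trial requires perturbation_deg"
            )
        if not needs_pert and self.perturbation_deg is not None:
            raise ScheduleError(
                f"{self.feedback_mode} trial must not carry perturbation_deg"
            )
        if self.movement_mode == "passive" and self.passive_hand_deg is None:
            raise ScheduleError("passive trial requires passive_hand_deg")
        unknown = set(self.probes) - set(PROBE_KINDS)
        if unknown:
            raise ScheduleError(f"unknown probes {sorted(unknown)}")


@dataclass(frozen=True)
class Schedule:
    """Ordered experiment design: a tuple of trials plus metadata."""

    trials: Tuple[TrialSpec, ...]
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        # block labels must be contiguous (no label may recur after a gap)
        seen, prev = set(), object()
        for spec in self.trials:
            if spec.block_label != prev:
                if spec.block_label in seen:
                    raise ScheduleError(
                        f"block label {spec.block_label!r} is not contiguous"
                    )
                seen.add(spec.block_label)
                prev = spec.block_label

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __add__(self, other: "Schedule") -> "Schedule":
        meta = {**self.metadata, **other.metadata}
        return Schedule(
            self.trials + other.trials,
            name=self.name or other.name,
            metadata=meta,
        )


def _block(n: int, label: str, **kwargs: object) -> List[TrialSpec]:
    return [TrialSpec(block_label=label, **kwargs) for _ in range(n)]  # type: ignore[arg-type]


def make_clamp_design(
    n_baseline: int,
    n_clamp: int,
    clamp_deg: float,
    n_washout: int,
    hand_reports: bool = False,
    probe_trials: Iterable[int] = (),
) -> Schedule:
    """Veridical baseline, error-clamp block, no-feedback washout.

    With ``hand_reports`` every trial carries a felt-hand-position report
    (the continuous-report variant of the clamp task).  ``probe_trials``
    lists trial indices (0-based, within the full schedule) that carry a
    passive localization probe at the target direction.
    """
    if min(n_baseline, n_clamp, n_washout) < 0:
        raise ScheduleError("block lengths must be >= 0")
    probes = frozenset({"hand_report"}) if hand_reports else frozenset()
    trials = (
        _block(n_baseline, "baseline", feedback_mode="veridical", probes=probes)
        + _block(
            n_clamp, "clamp", feedback_mode="clamp",
            perturbation_deg=float(clamp_deg), probes=probes,
        )
        + _block(n_washout, "washout", feedback_mode="none", probes=probes)
    )
    probe_set = set(probe_trials)
    for i in probe_set:
        if not 0 <= i < len(trials):
            raise ScheduleError(f"probe trial index {i} out of range")
        t = trials[i]
        trials[i] = TrialSpec(
            feedback_mode=t.feedback_mode,
            perturbation_deg=t.perturbation_deg,
            target_deg=t.target_deg,
            probes=t.probes | {"passive_probe"},
            probe_angle_deg=t.target_deg,
            block_label=t.block_label,
        )
    return Schedule(
        tuple(trials),
        name="clamp",
        metadata={"design": "clamp", "clamp_deg": float(clamp_deg)},
    )


def make_rotation_design(
    n_baseline: int,
    rotation_deg: float,
    n_rotation: int,
    n_aftereffect: int,
    gradual: bool = False,
    ramp_increment: Optional[float] = None,
) -> Schedule:
    """Contingent-rotation block (abrupt or ramped), then aftereffect block.

    A gradual design ramps the rotation by ``ramp_increment`` deg per
    trial until it reaches ``rotation_deg`` and then holds; the ramp must
    land exactly on the final rotation.
    """
    if min(n_baseline, n_rotation, n_aftereffect) < 0:
        raise ScheduleError("block lengths must be >= 0")
    trials = _block(n_baseline, "baseline", feedback_mode="veridical")
    if gradual and n_rotation > 0:
        if ramp_increment is None or ramp_increment <= 0:
            raise ScheduleError("gradual design requires ramp_increment > 0")
        n_ramp = abs(rotation_deg) / ramp_increment
        if abs(n_ramp - round(n_ramp)) > 1e-9:
            raise ScheduleError(
                f"ramp of {ramp_increment} deg/trial overshoots "
                f"rotation {rotation_deg} deg"
            )
        n_ramp = int(round(n_ramp))
        if n_ramp > n_rotation:
            raise ScheduleError("ramp longer than the rotation block")
        sgn = math.copysign(1.0, rotation_deg) if rotation_deg else 1.0
        for i in range(n_rotation):
            r = sgn * min((i + 1) * ramp_increment, abs(rotation_deg))
            trials.append(
                TrialSpec(
                    feedback_mode="rotation",
                    perturbation_deg=r,
                    block_label="rotation",
                )
            )
    else:
        trials += _block(
            n_rotation, "rotation",
            feedback_mode="rotation", perturbation_deg=float(rotation_deg),
        )
    trials += _block(n_aftereffect, "aftereffect", feedback_mode="none")
    return Schedule(
        tuple(trials),
        name="rotation",
        metadata={
            "design": "rotation",
            "rotation_deg": float(rotation_deg),
            "gradual": gradual,
        },
    )


def make_passive_exposure_design(
    final_deg: float,
    n_exposure: int,
    n_active_aftereffect: int,
) -> Schedule:
    """Robot-displaced hand with the cursor clamped at the target.

    The passive hand angle ramps linearly from ``final_deg/n_exposure``
    to ``final_deg`` over the exposure block while the cursor moves
    straight to the target (clamp at 0 deg); active no-feedback reaches
    follow to measure the aftereffect.
    """
    if n_exposure < 1:
        raise ScheduleError("n_exposure must be >= 1")
    trials = [
        TrialSpec(
            feedback_mode="clamp",
            perturbation_deg=0.0,
            movement_mode="passive",
            passive_hand_deg=final_deg * (i + 1) / n_exposure,
            block_label="exposure",
        )
        for i in range(n_exposure)
    ]
    trials += _block(n_active_aftereffect, "aftereffect", feedback_mode="none")
    return Schedule(
        tuple(trials),
        name="passive_exposure",
        metadata={"design": "passive_exposure", "final_deg": float(final_deg)},
    )


def run_schedule(
    schedule: Schedule,
    params: PremoParams,
    initial_state: Optional[ModelState] = None,
) -> List[TrialRecord]:
    """Noise-free forward simulation; one record per trial.

    Trials carrying a passive localization probe additionally emit
    ``probe_report``: the probe angle plus the current (global)
    proprioceptive shift.
    """
    state = initial_state if initial_state is not None else ModelState()
    records: List[TrialRecord] = []
    for i, spec in enumerate(schedule):
        try:
            state, rec = step_trial(state, spec, params)
        except Exception as exc:
            raise ScheduleError(f"trial {i}: {exc}") from exc
        if "passive_probe" in spec.probes:
            rec = TrialRecord(
                **{**rec.__dict__, "probe_report": spec.probe_angle_deg + rec.beta_p}
            )
        records.append(rec)
    return records
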