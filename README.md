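# premo

A simulator, analytic toolkit and parameter estimator for the
**proprioceptive re-alignment model (PReMo)** of implicit sensorimotor
adaptation, together with the classical visuo-centric state-space model
as a reference learner.

## The problem

When reaching movements receive perturbed visual feedback — a cursor
rotated relative to the hand, or *clamped* at a fixed angle from the
target regardless of where the hand goes — the motor system recalibrates
automatically. This implicit adaptation has a puzzling signature: its
rate and asymptote stop scaling with the size of the visual error, and
the asymptote (typically 15–25° in clamp experiments) is tightly linked
to *proprioception*: how far the felt hand position is dragged toward
the cursor, and how variable that felt position is.

PReMo explains this by replacing the visual error with a proprioceptive
one. Perceived hand position is built in two stages:

1. **Intramodal integration.** The afferent signal is averaged with the
   efference-copy prediction of the movement goal G:
   `x_p_int = w_p·x_p + (1 − w_p)·G`, with
   `w_p = σ_u²/(σ_u² + σ_p²)`; likewise for the cursor with `w_v`.
2. **Crossmodal recalibration.** The integrated hand estimate shifts
   toward the integrated cursor by `β_p = min(η_p·|Δ|, β_p,sat)` (and
   the cursor reciprocally by `β_v`, ceiling `β_v,sat ≈ 1°`), where Δ is
   the integrated visuo-proprioceptive discrepancy. The shift saturates:
   15° and 30° discrepancies both give the same ~5° shift.

Adaptation updates the sensorimotor map by `K ×` the *proprioceptive
error* — perceived target minus perceived hand — and stops when the
hand *feels* like it is at the (perceived) target:

```
|x_UB| = (β_p,sat + β_v,sat) / w_p  =  β_p,sat · (1 + σ_p²/σ_u²)   (β_v,sat = 0)
```

so the asymptote is invariant to clamp size above the saturation
threshold, grows with proprioceptive uncertainty, and shrinks with
prediction noise — none of which follows from the visuo-centric
equilibrium `x_UB = K·e/(1 − A)`.

## Worked example

```python
import dataclasses
from premo import (PremoParams, make_clamp_design, run_schedule,
                   upper_bound_saturated, saturation_threshold)

params = dataclasses.replace(PremoParams(), w_p=0.25, beta_v_sat=0.0)
schedule = make_clamp_design(10, 80, 15.0, 10)   # baseline, +15° clamp, washout
records = run_schedule(schedule, params)

clamp = [r for r in records if r.cursor_deg == 15.0]
print(f"first-trial felt hand:   {clamp[0].perceived_hand:+.2f} deg")
print(f"first-trial update:      {clamp[0].update:+.2f} deg")
print(f"adaptation after 80:     {clamp[-1].hand_angle:+.2f} deg")
print(f"closed-form upper bound: {upper_bound_saturated(params.beta_p_sat, params.w_p):.2f} deg")
print(f"saturation threshold:    {saturation_threshold(params.eta_p, params.w_v, params.beta_p_sat):.2f} deg")
```

prints

```
first-trial felt hand:   +5.00 deg
first-trial update:      -1.00 deg
adaptation after 80:     -19.65 deg
closed-form upper bound: 20.00 deg
saturation threshold:    13.89 deg
```

On the first clamp trial the hand is at the target but *feels* 5° off,
dragged toward the clamp (the saturated proprioceptive shift); that
felt error drives a 1° update (K·5°) away from the clamp. Over 80
trials the hand approaches the 20° bound — the point where the hand,
felt through `w_p = 0.25`, is perceived back at the target. The
threshold is the smallest clamp for which the first-trial shift is
already saturated; above it, learning curves for 15°–90° clamps are
identical. Angles are geometric (counterclockwise positive, target at
0°), so adaptation to a +15° clamp is negative; `premo ... --paper-signs`
converts output to the reporting convention (adaptation positive).

The package also ships schedule builders for rotation and
passive-exposure designs, a generalization module (start-position shift
geometry + Gaussian tuning), a synthetic-data generator
(`generate_dataset`) and least-squares fitting with parameter recovery
(`fit_model`, `recover_parameters`). A thin CLI exposes all of it:
`premo simulate|generate|fit|recover|analytic|generalize`.

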