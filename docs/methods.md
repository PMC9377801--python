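# Methods

## Model

One trial of the proprioceptive re-alignment model runs, in order:

1. **Cursor rule.** Veridical feedback: cursor = hand. Rotation r:
   cursor = hand + r. Clamp c: cursor = c, independent of the hand.
   No-feedback: cursor absent.
2. **Intramodal integration.** `x_p_int = w_p·x_p + (1 − w_p)·G`,
   `x_v_int = w_v·x_v + (1 − w_v)·G`, where G is the movement goal
   (the target, 0° by convention) and the weights are the reliability
   ratios `σ_u²/(σ_u² + σ_p²)` and `σ_u²/(σ_u² + σ_v²)`.
3. **Crossmodal recalibration.** With Δ = `x_v_int − x_p_int`:
   `β_p = sign(Δ)·min(η_p|Δ|, β_p,sat)`,
   `β_v = −sign(Δ)·min(η_v|Δ|, β_v,sat)`. Recalibration is
   instantaneous on every feedback trial (empirically the shifts reach
   asymptote within a few reaches) and follows the current discrepancy
   with no hysteresis. On no-feedback trials both shifts instead decay
   by `A_ret`.
4. **Perception.** `perceived hand = x_p_int + β_p`; the visual shift is
   global, so `perceived target = G + β_v` (and
   `perceived cursor = x_v_int + β_v`).
5. **Error and update.** `e = perceived target − perceived hand`;
   `x_p ← x_p + K·e`.

The driving error uses the *perceived* target rather than the physical
one. This is what makes the felt-hand plateau sit `β_v,sat` beyond the
target on the side opposite the clamp: the fixed point is perceived
hand = perceived target, i.e. `w_p·x* + β_p,sat = −β_v,sat`, giving
`|x*| = (β_p,sat + β_v,sat)/w_p`. Setting `β_v,sat = 0` recovers the
literal physical-target error.

**Passive trials** (robot-displaced hand, no motor command): there is no
efference copy, so the integrated estimates equal the actual positions
(equivalent to both weights at 1); the shifts recalibrate but the map
does not update and the planned reach direction is untouched. The
aftereffect that follows emerges on subsequent active reaches from the
residual shifts.

**No-feedback trials**: proprioception remains available without
vision, so by default the map keeps updating from the decaying residual
error (`update_without_feedback = True`); washout then emerges from
shift decay. Whether the update operates without a perturbation present
is not settled, so the behaviour is switchable — with it off, the hand
freezes whenever the cursor is absent.

## Sign conventions

Internally everything is a signed geometric angle: target at 0°,
counterclockwise positive. A +c clamp drives adaptation negative, and a
shift "toward" the other modality carries the sign of the discrepancy.
The bookkeeping used in behavioural reports (adaptation plotted
positive, toward-shifts negative) mixes magnitudes and directions and is
error-prone inside an update rule, so it is applied only at the
reporting layer (`to_paper_signs`, the `--paper-signs` CLI flag).

## Parameters and defaults

| name | default | units | meaning |
|---|---|---|---|
| `w_p` | 0.25 | – | proprioceptive integration weight; 0.25 ⇔ σ_p²/σ_u² = 3 |
| `w_v` | 0.9 | – | visual integration weight (vision far more reliable than the prediction) |
| `eta_p` | 0.4 | – | proprioceptive recalibration ratio below saturation |
| `eta_v` | 0.1 | – | visual recalibration ratio |
| `beta_p_sat` | 5.0 | deg | proprioceptive-shift ceiling (empirical ~5°) |
| `beta_v_sat` | 1.0 | deg | visual-shift ceiling (empirical ~1°) |
| `K` | 0.2 | – | learning rate on the proprioceptive error |
| `A_ret` | 0.95 | – | shift retention per no-feedback trial |

The defaults reproduce the headline magnitudes: a 5° proprioceptive and
1° visual shift for 15–30° discrepancies, and a 20° clamp asymptote in
the `beta_v_sat = 0` regime. Only the weight *ratios* are identifiable
from behaviour, so fitting is parameterized in (w_p, w_v), not raw
variances; variances may still be supplied to derive weights
(`PremoParams.from_variances`). Weights of exactly 0 are rejected (no
sensory contribution — the integration is undefined conceptually, and
the upper bound diverges). The decay parameter `A_ret` is kept distinct
from the baseline model's retention A; the two play different roles
(shift decay vs. state forgetting) and nothing forces them equal.

## Closed forms

* Saturated bound: `|x_UB| = (β_p,sat + β_v,sat)/w_p` — invariant to
  clamp size above the first-trial saturation threshold
  `c* = β_p,sat/(η_p·w_v)` (the hand starts at the target, so the
  discrepancy on trial 1 is `w_v·c`; `w_p` plays no role in c*).
* Unsaturated bound (small clamps, visual shift negligible): solving
  `(1 − η_p)·w_p·x = −η_p·w_v·c` gives
  `|x_UB| = η_p·w_v·|c| / ((1 − η_p)·w_p)`. This form was derived from
  the equilibrium condition and validated against fixed-point
  simulation rather than transcribed, and the implementation refuses to
  apply it when the shift implied at equilibrium,
  `η_p·w_v·|c|/(1 − η_p)`, reaches the ceiling (a `RegimeError`
  redirects to the saturated bound).

Both agree with long-run noise-free simulation to 1e-6 over randomized
parameter draws (property-tested). Sensitivity directions follow
directly: the bound rises with σ_p², falls with σ_u², and falls with
σ_v² only below saturation.

## Baseline learner

`x[t+1] = A·x[t] + K·e[t]` with the visual error e defined per paradigm:
clamp → constant c; contingent rotation → (x + r) − target; veridical →
x − target; no feedback → retention only. The literal step and the
`K·e/(1 − A)` equilibrium are kept in the convention where adaptation is
measured positive; the schedule-level simulator runs in the geometric
convention, where compensation opposes the signed error (a sign flip,
nothing more). The contrast property — the baseline asymptote scales
with clamp size, the saturated proprioceptive bound does not — is the
model comparison the package is built around.

## Generalization

The far (global) component treats the start-position shift as a
workspace *translation* (a 2-vector): movements are planned from the
perceived (shifted) start to each probe target at reach amplitude L, and
executed from the actual start, deviating the heading by the angle
between the planned vector and the probe direction. Whether that shift
is angular or translational — and whether it equals the shift at the
target — is untested empirically, so the vector is an independent input
rather than being derived from `β_p`. Deviations vanish along the shift
axis and are antisymmetric about it. The local component is a Gaussian
tuning kernel around the trained direction; its width is unconstrained
by available evidence and defaults to 30°, exposed as a parameter. The
total predicted pattern is the sum of the two components.

## Synthetic data

`generate_dataset` emulates a multi-subject experiment: per-subject
parameters drawn from truncated Gaussians around group values, motor
noise on every active reach, and report/probe noise on the measurement
channels. Motor noise is *execution* noise: the noisy reach is what the
senses register — it deflects the cursor on contingent trials (not on
clamps, whose cursor is fixed by design) and feeds the error that
updates the next trial — but it is not stored in the sensorimotor map.
The persistent alternative (noise accumulating in the map) turns the
trajectory into a random walk, which is not how single-subject clamp
series look. All noise is Gaussian; heavy-tailed lapses, trial-order
effects, target-location effects and any temporal-delay dependence of
recalibration are not modelled, so passing tests say nothing about
those aspects of real data. Generation is byte-reproducible from the
integer seed.

## Fitting and recovery

Least squares on the (group-mean) hand-angle series, plus the felt-hand
report series when present, equally weighted; R² = 1 − SSE/SST with SST
about the observed means. Bounded L-BFGS-B from the base parameter
values plus seeded uniform random starts (default 10); convergence when
the relative loss change falls below 1e-10 or the projected gradient
below 1e-10; more starts can only lower the final loss. On hand angles alone, (w_p, β_p,sat) lie on a
ridge (only their ratio is constrained by the asymptote) and the fitter
warns; reports break the ridge because the early report bias is
+β_p,sat and the plateau is −β_v,sat directly.

The recovery harness simulates with noise, refits, and tabulates bias
and RMSE per parameter. The reference recovery condition is the
continuous-report clamp design — 80 trials at 15° with a report every
trial, 1° motor and report noise, one subject per replicate — under
which (K, w_p, β_p,sat, β_v,sat) recover with RMSE well below 20% of
truth.

## Numerical choices and problem sizes

Noise-free clamp simulations use 500–800 trials; the slowest contraction
rate in the tested parameter ranges leaves the residual far below the
1e-6 agreement tolerance used throughout. Ties at Δ = 0 produce exactly
zero shift. Gradual ramps are linear per trial and must land exactly on
the final perturbation (overshoot is a schedule error). Empty schedules
are legal and yield empty record lists. Angles in files must lie in
(−180, 180]; wrapped values are normalized with a warning.

## Known limitations

* No temporal dynamics: feedback delays, movement kinematics and online
  corrections are out of scope.
* Awareness and strategic re-aiming are not modelled beyond what
  parameter scaling can express.
* One target direction per schedule; multi-target designs reduce to
  per-target bookkeeping that the schedule metadata does not automate.
* The empirical learning curves behind published group fits exist only
  as figures; the fitting machinery is validated by self-consistency
  and recovery on synthetic data instead.
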