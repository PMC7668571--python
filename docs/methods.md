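# Methods

## The lumped network model

A pressure-controlled ventilator, its tubing and one patient are reduced to a
four-element linear network:

```
 p(t) ---[ Rv + Rr ]---+---[ R ]---+
 (ventilator drive)    |           |
                      Cv           C
                       |           |
                      ref         ref
```

* `Rv` — tubing flow resistance, cmH2O/(L/s) (includes the circle-system
  non-return valves and HME filter);
* `Rr` — a deliberately added flow restrictor, present only in the phase
  where it is physically placed (by default the inspiratory limb);
* `Cv` — tubing compliance, L/cmH2O (gas compression plus hose distension);
* `R`, `C` — patient airway resistance and lung compliance.  Each may take
  different values in inspiration and expiration, giving up to eight
  parameters per patient.

In pressure-control mode the drive `p(t)` is modelled as an ideal square
wave: `PEEP + Pinsp` for the inspiratory fraction of the breath
(`t_insp = (60/RR) / (1 + E)` with I:E = 1:E) and `PEEP` for the remainder.
Ramps, flow limits and triggers are deliberately outside the model.

With state `x = (p_tube, p_lung)` — the pressures across `Cv` and `C` — each
phase is an affine LTI system

```
Cv dp_tube/dt = (p - p_tube)/(Rv + Rr) - (p_tube - p_lung)/R
C  dp_lung/dt = (p_tube - p_lung)/R
```

whose equilibrium is all pressures equal to the drive.  `Cv = 0` is handled
by an explicit one-state code path (time constant `(Rv + Rr + R) C`), not by
a small-epsilon hack.

## Cyclic steady state

One breath is the composition of two matrix-exponential flow maps,
`Phi_i = exp(A_i t_insp)` and `Phi_e = exp(A_e t_exp)`.  The breath-to-breath
periodic solution satisfies `x0 = Phi_e Phi_i x0 + const`, a 2x2 (or 1x1)
linear fixed point solved directly; both phase matrices are Hurwitz, so the
cycle map is a contraction and the fixed point exists and is unique (the
solver still guards the solve against ill-conditioning).  No transient
integration or iteration is involved.

Tidal volume is `C` times the peak-to-peak lung pressure over the cycle.  One
subtlety matters at the 0.3% level: the lung-pressure extrema do **not** sit
at the switch instants.  At the start of expiration `p_tube` is still above
`p_lung`, so the lung keeps filling briefly (and keeps emptying briefly into
inspiration).  The extrema are located exactly by root finding on the patient
flow within each phase (bracketed scan plus Brent refinement) rather than
read off the sampled grid.  Equivalently, vt is the integral of positive
patient flow over the cycle, and a test asserts the two agree to 1e-6 L.

Waveforms are sampled on a 1000-point grid per cycle by default; the grid is
presentation only — vt and the periodicity condition are grid-independent.

### Numerical oracle

`simulate_transient` integrates the same switched system with fixed-step RK4
from an arbitrary initial state, stopping when the cycle-start state changes
by less than 1e-9 cmH2O per cycle (the default step is 1 ms; a step too
large for the fast time constant blows up and is reported through the
residual, never silently).  It shares no code path with the matrix-
exponential solver and is used in tests as an independent oracle: over
random parameter draws the two agree on vt to better than 1e-4 L, and with
`Cv = 0` the solver reproduces the closed-form single-compartment volume

```
vt = Pinsp C (1 - e_i)(1 - e_e) / (1 - e_i e_e),   e = exp(-t_phase / tau)
```

to 1e-9 L.

## Restrictor sizing

vt is smooth, strictly decreasing in the added inspiratory resistance and
cheap to evaluate, so the inverse problem — the resistance delivering a
target volume — uses bracketed bisection: initial bracket [0, 50]
cmH2O/(L/s), doubled until it straddles the target, capped at 1000.
Tolerance is expressed in litres (default 1e-4 L) because the clinically
relevant error is in delivered volume.  A target above the unrestricted
volume raises an error naming that volume; it is never clamped.

## Component characterisation

**Restrictor law.**  Pressure drop vs mean flow is fitted with
`dp = K2 q^2 + K1 q + K0` (turbulent + laminar losses), the linear
restriction `K2 = 0`, or the proportional one `K2 = K0 = 0`, in which case
`K1` is the component's resistance — the only representation the dynamic
model can absorb.  Robust fitting is iteratively reweighted least squares
with Tukey bi-square weights, tuning constant 4.685 (95% Gaussian
efficiency), at most 100 iterations, coefficient convergence 1e-8; plain
least squares is available and coincides with the robust fit on well-behaved
data.  For the no-intercept model the reported R^2 is computed against the
uncentred total sum of squares (the centred variant is also reported, since
published R^2 values for constrained fits are convention-dependent).
Confidence intervals are the analytic 95% intervals of the final weighted
fit; no bootstrap.

**Lung R and C.**  From a co-registered pressure/flow recording covering at
least three breaths, the single-compartment pressure balance

```
p(t) = p0 + R q(t) + V(t)/C
```

is fitted by least squares, with `V` the running trapezoidal integral of
flow.  Breath onsets are detected as rising crossings of the pressure
midline; a piecewise-linear baseline anchored at the onsets is subtracted
from `V` to remove integration drift (a random walk under flow noise)
without touching the within-breath volume excursion.  A non-positive
compliance estimate is rejected, never returned.

**Tubing Cv.**  With the line blocked, integrated flow tracks node pressure
exactly (`V = const + Cv p`).  Per breath, the plateau and trough are taken
as the samples in the top and bottom quartile of the pressure swing, and Cv
is the through-origin regression slope of the plateau-minus-trough volume
differences on the corresponding pressure differences.  Averaging over
plateau/trough samples avoids assuming where within a sampling interval the
phase switch fell.  A pressure swing under 1 cmH2O is reported as
unreliable rather than estimated.

## Synthetic recordings

`generate_synthetic` emulates what two bench loggers would record: the
steady-cycle patient flow, tubing-node pressure and lung volume sampled at
50 Hz (the bench loggers' rate), independent Gaussian noise per channel
(defaults 0.1 cmH2O on pressure, 0.01 L/s on flow — typical flow-analyser
noise), and a start-time offset between the loggers.  All randomness comes
from one seeded generator; fixed seed gives byte-identical files.
`synthetic_blocked_line` produces the corresponding blocked-tubing run from
the closed-form one-state solution.  Co-registration recovers the offset as
the integer-sample lag maximising the cross-correlation of a shared channel,
searched within ±10 s.

What the generator does *not* emulate: ventilator pressure ramps and flow
limiting, valve cracking-pressure nonlinearity, sensor drift and
quantisation, and any coupling between two patient branches.  Passing the
recovery tests therefore shows the estimators are correct for the model
class and robust to additive noise — not that the model class captures every
feature of real recordings.

## Problem sizes and numerical choices

* Default waveform grid 1000 samples/cycle; oracle step 1 ms; transient
  convergence tolerance 1e-9 cmH2O per cycle.
* Recovery tests use 10-12 breaths per recording, matching a bench run of
  ~15 cycles per setting.
* 50 Hz resolves lung-scale time constants (~1.4 s) but not the blocked-line
  tubing transient (`Rv Cv ≈ 0.09 s`, ~4 samples), so blocked-line synthetic
  runs are sampled at 200 Hz; the noise-free exactness test for the R/C
  estimator samples at 2 kHz, where trapezoid quadrature of the
  discontinuous flow at the phase switches is negligible.
* Zero patient resistance is rejected as ill-posed (with tubing compliance
  the state matrix is singular there); zero series resistance with tubing
  compliance likewise.
* Units are fixed package-wide (cmH2O, L, s, cmH2O/(L/s), L/cmH2O,
  breaths/min); there is no unit-conversion layer.

## Known limitations

* The restrictor enters the dynamic model only as a linear resistance; the
  quadratic law exists only in the characterisation module.  For a strongly
  orifice-like device the proportional `K1` is flow-range dependent.
* Each patient branch is solved independently; the small measured
  cross-effect between branches (a restricted branch slightly raising the
  other's volume) is outside the model.
* The validation harness reproduces published bench predictions to within
  ~1%; the residual reflects reconstructing the network from the published
  description rather than the original equations, and bounds how closely the
  derived per-case error statistics can match the published ones.
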