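# Methods

## Respiratory mechanics model

The lung is a single linear compartment: volume `V` above functional residual
capacity, compliance `C`, airway resistance `R`, driven by the pressure at the
airway opening and by pleural pressure `P_pl`:

```
dV/dt = (P_aw − P_alv)/R,    P_alv = V/C + P_pl
```

Defaults (`LungParams`): `C = 25 ml/mbar`, `R = 0.02 mbar·s/ml`,
FRC 1000 ml, expiratory valve resistance 0.02 mbar·s/ml. These are plausible
adult-pig magnitudes chosen so that a 60 mbar / 205 ms pressure-controlled
breath delivers a physiologically small tidal volume (~230–380 ml depending
on the end-expiratory state) and a 7 ml/kg constant-flow breath peaks at
~30 mbar under concurrent compressions. No claim is made that they match any
particular animal; linearity means all results scale with `C` and `R·C`.

During expiration the circuit is open to PEEP through the expiratory valve,
modelled as a series resistance `R_valve`. The proximal pressure sensor sits
between the valve and the airway resistance, so its reading during expiration
is a resistive divider of the alveolar excursion:

```
P_sensor = PEEP + (P_alv − PEEP) · R_valve/(R + R_valve)
```

This is the mechanism by which chest compressions become visible at the
airway opening while the expiratory valve is open, and hence the physical
input of the CCSV inverse trigger. With the defaults the divider passes half
of the alveolar excursion. `R_valve` is a free design parameter: at 0 the
trigger would see nothing, and the mode could not work.

## Chest-compression driver

`CompressionProfile`: rate 100/min, duty fraction 0.5, peak pleural rise
15 mbar, trapezoid waveform with 50 ms ramps (a half-sine option exists; its
onset slope is gentler, so lower gradient thresholds are needed with it).
The pleural amplitude of a piston device is not observable directly and is
treated as a free parameter; 15 mbar makes the expiratory airway excursion
(~7 mbar) comfortably exceed the whole adjustable trigger-level range, and
the ramp slope (300 mbar/s pleural, ~140 mbar/s at the sensor) exceed the
default gradient threshold, which is what a clinically usable trigger
setting requires.

## Controllers

**CCSV.** The inverse trigger fires when, at the same sample, (1) sensor
pressure exceeds `PEEP + level`, (2) the backward-difference pressure
gradient over a 5 ms window reaches the threshold, and (3) the expiration has
lasted at least the minimum expiratory time. All three parameters are
confined to the device's adjustable ranges (0.9–3.7 mbar, 25–375 mbar/s,
200–340 ms); the defaults (1.5 mbar, 100 mbar/s, 210 ms) sit mid-range, since
the specific values used in any one experiment are a user setting, not a mode
property. On trigger the controller commands the preset plateau instantly
(the lung's `R·C` shapes the delivered waveform) and cycles off after exactly
the preset inspiratory time; triggers during inspiration are ignored, so the
minimum-expiration criterion acts as a refractory period by construction.
The gradient estimator (two-point backward difference, 5 ms smoothing
window) is a design choice: the criterion is defined physically ("pressure
rises fast enough"), not algorithmically.

**IPPV.** Constant inspiratory flow `V_T / T_insp`, passive expiration to
PEEP. The 60 mbar upper pressure limit throttles flow proportionally within
a 2 mbar margin below the limit (plus a hard cap in the integrator); the
breath is never cycled off early. This matches a limit that in practice is
never reached rather than a pop-off that dumps the breath.

## Integration and sampling

Explicit fixed-step integration at 1 ms, using the exact discretization of
the linear ODE over each step with inputs frozen (so a constant-pressure step
response reproduces the closed-form exponential to machine precision, and
there is no adaptive-step nondeterminism). The controller runs on the same
1 ms grid — the 205 ms cycling time needs finer resolution than the output
rate. Output is decimated to 100 Hz, the standard physiological recording
rate: pressures and volume are the instantaneous values at the end of each
10 ms block, flow is the block mean, so that `cumsum(flow)/f_s` reproduces
the volume trace exactly on the output grid. Event timestamps stay on the
1 ms grid; an inspiration-end stamp marks the end of the last pressurized
step, so logged inspiration durations equal the preset cycling time.

## Protocol layer

The allocation enumeration, balanced randomization (multiples of 6 subjects)
and the 3 + 5×4 min timeline are implemented literally. The untreated-VF
interval has no ventilation and no compressions and is carried as timeline
metadata only; blood-gas sampling instants likewise. Per-period summaries
(breath count and rate, median peak pressure, minute ventilation,
synchronization fraction) are computed from the simulated traces. MAP/CVP
slots exist in the summary for recorded vascular traces; the simulator does
not generate them (below).

## What the synthetic data do and do not represent

Two generators exist and both are study-condition emulators, not physiology:

* the **mechanics simulator** reproduces the *controller-side* behavior —
  trigger timing, cycling, pressures, volumes, synchronization — under ideal
  sensors plus optional Gaussian sensor noise. It contains no gas exchange
  and no circulation, so oxygenation (PaO₂), decarboxylation (PaCO₂) and
  blood pressures are *not* emergent quantities here; they exist in animals,
  not in this model.
* the **cross-over table generator** draws per-subject values as
  `location_t + subject_effect + noise` (multiplicative/log-normal for
  right-skewed variables such as PaO₂), with default locations and spreads
  set to the magnitudes reported for 12-animal swine CPR cross-over
  experiments. It emulates the *shape* of such a dataset — 12 × 5 complete
  matrix, subject correlation, skew — so the statistical pipeline can be
  exercised end to end. Passing tests therefore validate the arithmetic of
  the analysis, never any biological claim.

## Statistical conventions

* Descriptives: median, 25th/75th percentiles by linear interpolation
  between order statistics (the convention is a documented choice), min, max.
* Friedman test: mid-ranks within subjects, tie-corrected statistic
  `(k−1)·Σ(R_j − n(k+1)/2)² / (Σr² − nk(k+1)²/4)`, df `k−1`. The p-value is
  chi-squared by default; the permutation path enumerates all `(k!)^n`
  per-subject rearrangements when that count is ≤ 100 000 and otherwise uses
  Monte-Carlo sampling with the add-one estimator `(1+b)/(1+B)`, which keeps
  the test valid (never anti-conservative) at any resample count.
* Post-hoc: exact two-sided Wilcoxon signed-rank per pair. Zero differences
  are dropped (an all-zero pair is flagged degenerate with p = 1), tied
  absolute differences get mid-ranks, the null distribution of `W⁺` is built
  by dynamic programming over doubled (hence integer) ranks, and the
  two-sided p doubles the smaller tail, capped at 1. A Conover rank-based
  alternative (`posthoc="conover"`) is provided; the choice of post-hoc test
  after a Friedman omnibus is genuinely open in the literature, and the
  signed-rank default matches the fully nonparametric framing.
* Bonferroni-Holm: step-down `max_j≤i (m−j+1)·p_(j)`, capped at 1, returned
  in input order.
* Power: no closed-form repeated-measures power formula is implemented (any
  such formula needs a correlation structure that observational tables do
  not determine); `estimate_power` estimates power by simulation from the
  generator instead.

## Problem sizes

Unit and property tests run simulations of 5–60 s (acceptance-style checks
use the full 60 s / 100-compression minute) and statistical checks at the
study size n = 12, k = 5; exhaustive oracles (permutation enumeration,
sign-flip enumeration) run at 4×3 and n ≤ 10, where they are exact and cheap.
The type-I-error check uses 2000 null simulations with 200 permutation
resamples each. The protocol CLI defaults to the full 4 min periods;
protocol tests use shortened periods, which exercises the identical code
path.

## Known limitations

* No gas exchange, no hemodynamics: physiological outcomes cannot be and are
  not simulated.
* Linear, single-compartment mechanics: no volume-dependent compliance,
  airway closure, or gas compressibility; compression-induced pleural
  pressure is imposed, not derived from chest-wall mechanics.
* The pleural amplitude and expiratory valve resistance are free parameters;
  synchronization results should be read as "for settings within the stated
  ranges there exist realistic signal conditions giving 1:1 triggering", not
  as a claim about any particular device pairing.
* Carry-over between protocol periods is not modelled (each period starts
  from rest); the cross-over analysis layer likewise ignores period effects,
  matching the nonparametric pipeline it reproduces.
* Legacy binary spreadsheet ingest (.xls) depends on an Excel reader being
  available to pandas; CSV and .xlsx are the supported interchange formats.
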