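# Methods

## The problem

Long-term wrist actigraphy with a light sensor yields weeks of 2-min-epoch
activity counts and illuminance, plus diary sleep times and (weekly) urinary
aMT6s acrophases.  The question the pipeline answers is *why* an
individual's sleep is long, late, variable or not synchronized to the 24-h
day: is the cause endogenous (a long intrinsic circadian period, a low
drive for wakefulness) or environmental (insufficient daytime light, too
much evening light)?  The package answers it by fusing the recordings with
a physiological model of sleep-wake regulation, and then uses the fitted
model to design light-availability interventions that restore 24-h
entrainment at a target wake time.

## Model

The simulation couples three standard components in the sleep-modeling
literature:

* **Sleep-wake flip-flop.**  Mean voltages `V_v` (sleep-active) and `V_m`
  (wake-active) with sigmoid firing rates
  `Q_i = Q_max / (1 + exp((theta - V_i)/sigma))` and mutual inhibition
  (`nu_vm Q_m` drives `V_v`, `nu_mv Q_v` drives `V_m`); time constants
  `tau_v = tau_m = 10 s`.  Wake is read out as `Q_m > Q_v` (equivalently
  `V_m > V_v`); the flip-flop's bistability supplies hysteresis, so no
  extra threshold parameter exists.
* **Homeostat.**  `chi dH/dt = mu Q_m - H`: sleep pressure charges during
  wake and discharges during sleep (`chi = 45 h`).
* **Circadian pacemaker and phototransduction.**  A van der Pol-type limit
  cycle `(x, x_c)` with a 7th-order amplitude nonlinearity (stiffness
  `mu_p = 0.13`), period set by the `(24/(f tau_c))^2` term with
  `f = 0.99669`, and photic drive
  `B = G alpha(I) (1 - n)(1 - b x)(1 - b x_c)` where
  `alpha(I) = alpha_0 (I/I_0)^p` and `dn/dt = 60 [alpha(I)(1 - n) - beta n]`
  describes the activated photoreceptor fraction.  Light reaches the retina
  only during model wake.

The total drive to the sleep-active population is
`D_v = nu_vh H + nu_vc C(x, x_c) + A_v - delta_D` with circadian drive
`C = (1 + 0.8 x - 0.47 x_c)/2`.  The per-cycle minimum of `C` is the
circadian wake-propensity minimum (CWPM), the model's phase marker; the
aMT6s acrophase is predicted as CWPM plus a fixed offset.

Two parameters are individual-specific and fitted: the intrinsic period
`tau_c` (h) and `delta_D`, the deviation of the mean wake drive from its
default (mV; larger values mean more wake and shorter sleep).  All other
parameters are fixed at the standard literature values for this model
family and were verified against structural requirements rather than tuned
to data: in constant darkness the pacemaker period reproduces `tau_c`
within 0.02 h across 23.8-24.8 h (this fixes the `mu_p = 0.13` /
`f = 0.99669` pairing); at `delta_D = 0` under a regular bright routine the
model sleeps ~8.8 h in one consolidated episode per day with wake around
07:50; and mean sleep duration is strictly decreasing in `delta_D`.

## Numerical integration

`tau_v = tau_m = 10 s` makes the system stiff, but each stiff equation is
linear once its inputs are frozen.  The integrator therefore advances
`V_v`, `V_m` and `H` with an exponential predictor-corrector (the linear
decay handled exactly, the nonlinear inputs to second order), the
photoreceptor pool exactly at frozen light, and the pacemaker pair with an
explicit midpoint step; the substep is `epoch/24 = 5 s` by default.  Light
is piecewise constant per 2-min epoch and gated by the current wake state;
when a wake/sleep transition is detected inside a substep the crossing time
is located by linear interpolation and the substep is re-integrated in two
pieces so the light gate switches at the transition itself.  Halving the
substep moves episode onsets by ~30 s and changes durations by under 0.1
min; the residual step dependence is a uniform phase offset that cancels
identically in parameter fitting because synthetic data and candidate
models share the integrator.  The default initial state is the entrained
steady state of the default physiology under a regular bright routine,
computed once per process by a 30-day spin-up and indexed by clock time;
simulations discard a 14-day transient before computing any summary.

## Rhythm metrics

The period estimator folds a signal at candidate periods from 20 to 28 h in
steps of one epoch (2 min) and reports the candidate minimizing the
residual variance — the pooled within-phase-bin sum of squares divided by
the total sum of squares, a unit-free quantity in [0, 1] invariant under
affine transforms of the signal (so the choice of raw vs transformed counts
cannot change the argmin).  Ties break to the smallest period; bins with
fewer than two samples contribute zero within-bin variance and are counted
in a sparsity diagnostic; `depth` (min/median residual variance) near 1
flags a structureless scan.  Sleep timing uses circular statistics (times
mapped to angles by `2 pi t/24`): circular mean, resultant length `R`,
variance `1 - R` and SD `(24/2 pi) sqrt(-2 ln R)`.  Light metrics are
computed per calendar day on non-missing epochs — hours with lux strictly
above 500, mean lux, mean `log(lux + 1)` — and summarized as medians across
days.  Missing epochs are excluded from every metric rather than
zero-filled, because zero lux is meaningful darkness.

## Fitting

The objective is
`J = circ_dist(model mean mid-sleep, observed)^2 + (model mean duration -
observed)^2` on an hours-squared scale (equal weights), with model
statistics taken from a simulation driven by the participant's own recorded
lux in imposed mode (observed light still masked during model sleep, since
closed eyes see no light).  A deterministic coarse grid (0.1 h x 0.25 mV
over tau_c in [23.5, 25.5] and delta_D in [-4, 2]) is followed by
Nelder-Mead refinement; no randomness is involved.  Two landscape features
required care:

* **Aliasing.**  `J` can be near zero in more than one basin — a drifting
  (non-24-h) model can match the circular-mean mid-sleep and duration of an
  entrained one, and vice versa.  Every near-optimal basin is therefore
  refined separately, and candidates whose final objectives are within a
  tolerance of the minimum are discriminated by how well the simulated
  onset period matches the observed onset drift (the drift rate is measured
  from the same diary data and is a sharp discriminator: its regression SE
  over four weeks is under a minute, while rival basins differ by tens of
  minutes).  The tie tolerance is wider when the observed onsets drift,
  because the circular mean of spread-out times has a higher noise floor
  than that of an entrained sleeper.
* **Narrow basins for free-runners.**  For a non-entrained participant a
  tau_c error of 0.05 h accumulates ~1.4 h of onset drift over the analysis
  window, so the true basin can fall between coarse-grid nodes.  When the
  observed onsets drift by more than 2 min/day the grid is supplemented by
  a fine tau_c scan (0.02 h) around the best drive value.

The coarse stages run at a reduced substep count (epoch/8); the phase bias
this introduces is far below the grid resolution, and refinement and final
scoring use the full-accuracy integrator.  Acrophase data never enter the
objective; they validate the fitted model via the circular correlation,
RMSE and regression slope between CWPM-based predictions and observations,
with each observation matched to the prediction inside its collection
window.

## Interventions

An available-light profile is a 24-h periodic raised-cosine day bump:
floor `L_eve` overnight, climbing from 07:00 to a maximum `L_day` at 13:00
and returning to the floor by 21:00 (all three clock times configurable;
the cosine half-waves fix the transition widths).  The model samples the
profile only when awake — interventions change the environment, never force
a wake time.  A (L_day, L_eve) grid point is classified entrained when the
sleep-onset period over the final 28 post-transient days is within 2 min of
24 h (the model gives no tolerance-free boundary; 2 min is one data epoch).
The default design grid is 67 x 67 log-spaced points, L_day in [10, 2000]
lux and L_eve in [0.5, 100] lux (~4500 simulations); tests and the
acceptance script use 12x12-15x15 grids, which resolve the boundary and its
monotonicity at ~150-lux resolution.  `design_intervention` returns all
entrained points whose circular-mean sleep offset is within a tolerance of
the target wake time, ordered by total (L1) intensity change from a
reference profile.

A caveat observed in simulation: a profile with almost no day/evening
contrast (e.g. 10 lux day over a 5 lux floor) is a near-zero-strength
zeitgeber, and even a `tau_c = 24.0` individual then shows a slow relative-
coordination wobble that the 28-day period regression scores a few minutes
off 24 h.  Entrainment claims are therefore meaningful only for profiles
with real modulation depth; the default grids satisfy this.

## Synthetic cohort

No public recordings exist for the population of interest, so the generator
is a first-class module with known ground truth.  Each participant draws
`tau_c` from a shared normal distribution (24:13 ± 0:11 h:m, clipped to the
physiologically plausible 23.9-24.9 h) — shared because fitted periods do
not differ between groups — and `delta_D` from a group distribution
(cases −1.82 ± 1.62, controls 0.66 ± 0.62, clipped to [−3.8, 1.9]).  The
participant's environment is an availability profile (cases 160/30 lux,
controls 600/15 lux by default; seasonal variants 160/30 with a short
winter day and 1000/10 with a long summer day), shifted day-by-day by a
behavioral jitter (SD 0.5 h) on the profile clock.  The model is simulated
in self-selected mode and the observables are synthesized from it:

* lux = availability during model wake × log-normal noise (sigma 0.3), at a
  0.1-lux sensor floor during sleep;
* activity = negative-binomial counts (wake mean 250/epoch, sleep mean
  10/epoch, dispersion 1.5);
* diary = model episodes + independent N(0, 15 min) onset/offset jitter;
* weekly acrophases = CWPM + 0.5 h + N(0, 30 min), inside 48-h windows.

The noise levels are plausibility choices, configurable in `CohortConfig`.
The tau_c draw depends only on (seed, participant index), never on group,
so permuting group labels provably leaves the pooled period distribution
unchanged.  What the generator does *not* emulate: device artifacts
(off-wrist detection, spectral response), naps and fragmented sleep beyond
what the deterministic model produces, within-individual day-to-day
variability of the physiology itself (variability enters only through the
light input and the reporting noise), and DST transitions (the calendar is
DST-free).  Passing recovery tests therefore demonstrates that the
estimation machinery is correct and well-conditioned under realistic noise,
not that the model captures every feature of real actigraphy.

## Problem sizes and tolerances

Tests and the acceptance script use 42-day recordings (matching the 6-week
protocol the pipeline targets), 20-participant recovery studies, 60-day
dark runs for period fidelity, and 12x12-15x15 design grids.  Key numeric
choices: entrainment tolerance 2 min on the onset period; free-running
fidelity tolerance 0.02 h; recovery tolerances ±6 min on tau_c and ±0.2 mV
on delta_D; optimizer `xatol = 1e-3`.  Degenerate inputs raise typed
errors (constant signals, all-masked days, too-few episodes) or return
flagged results (zero resultant length, non-oscillatory trajectories)
rather than numbers that look valid.

## Known limitations

The model is deterministic between days, so it cannot reproduce the
irregularity of real sleep beyond what variable light exposure induces;
REM/NREM architecture, napping and the acute alerting effect of light are
out of scope.  The acrophase offset is a single calibrated constant, not an
individual parameter.  Fitting estimates exactly two parameters; all other
physiology is assumed shared across individuals.
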