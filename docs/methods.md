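# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic machinery does and does
not establish about real data.

## Model structure

The simulator integrates nine states per subject over a 00:00–24:00 clock
axis in minutes: the Bergman triple (I, X, G), the exercise filters
(Gprod, Gup, Ie, PVO2max), the integrated intensity A, and the
glycogenolysis decline Ggly.

**Pancreatic release term.** The insulin equation uses
`+γ·[G − h]⁺·t_ref`. Two readings were open:

- *Sign.* Releasing insulin must raise I when glucose exceeds the β-cell
  threshold; the positive sign follows the classical healthy-subject
  minimal-model lineage. The opposite sign would make every meal suppress
  insulin, drive X negative and let glucose diverge — incompatible with the
  behavior the model is meant to produce (post-meal rise and return to
  baseline).
- *The time multiplier.* The classical term multiplies by elapsed time
  since a glucose challenge. A global clock diverges over 24 h, so `t_ref`
  is the time since the most recent meal onset, reset at each meal and zero
  before the first. With the threshold defaulting to `h = Gb`, the positive
  part gates the term off in the fasted state, making
  `(Ib, 0, Gb, 0, …, 0)` an exact rest equilibrium. Both `h` and the reset
  policy are configurable.

**Basal oxygen consumption.** The exercise filters are driven by PVO₂max
*above basal*. Heart-rate-derived intensity `u = 100·HR/HRmax` is absolute,
and a resting subject consumes about 8 % of PVO₂max, so the model input is
`u_eff = max(u − u_basal, 0)` with `u_basal = 8`. Without the offset,
resting heart rate would drive perpetual exercise fluxes and no rest
equilibrium would exist.

**Glycogen depletion logic.** While exercising, A accumulates at rate
`u_eff`; when A reaches `ATH(u_eff) = max(−1.152 u² + 87.471 u, 0)` the
glycogenolysis decline Ggly grows at constant K. At rest, A resets rapidly
(first-order, time constant 0.001 min — the fast-reset reading of the
recovery branch; the coefficient is configurable) and Ggly recovers with
time constant T1. ATH is treated as a threshold on A in the same %·min
units.

**Units bridging.** Gprod, Gup and Ggly are mg/kg/min. Multiplying by body
weight W (kg) gives mg/min; dividing by the glucose distribution volume
VolG (dL) yields mg/dL/min, matching dG/dt. Meal grams convert to
concentration by `1000 mg/g ÷ VolG`, which makes the absorption kernel a
unit-mass density in time (its integral is exactly 1 per compartment); a
bioavailability multiplier defaults to 1. Per subject, `VolG = 1.67 dL/kg ×
weight` (~117 dL at 70 kg).

## Parameters

Rate constants are not fully identifiable from daily-life data, so defaults
ship in a version-controlled YAML (`glycosim/data/default_params.yaml`,
units sidecar included) and every value is overridable.

| group | values | provenance of the default |
|---|---|---|
| Bergman core | p1 = 0.0317, p2 = 0.0123, p3 = 4.92·10⁻⁶, η = 0.2659 | classical healthy-subject minimal-model constants |
| release gain | γ = 0.02, h = Gb | calibrated (below) |
| exercise | a1 = 0.00158, a2 = 0.056, a3 = 0.00195, a4 = 0.0485, a5 = 0.00125, a6 = 0.075, K = 0.0108, T1 = 6 | the exercise-subsystem source model, kept verbatim |
| absorption | r1 = 0.007, r2 = 0.009 (slow), r3 = 0.028, r4 = 0.035 (fast) | calibrated (below) |
| basal | Gb = 85 mg/dL (per-subject), Ib = 7 µU/mL, u_basal = 8 % | typical fasting physiology |

**Calibration.** γ and the slow-absorption rates are free in the published
formulation. They were fixed once so that a healthy 70 kg subject eating a
single ~85 g slow-carbohydrate meal peaks ~25 mg/dL above basal about an
hour after intake and returns to baseline — ordinary postprandial
physiology — which also places seeded active-male cohorts (~300 g
carbohydrate/day over 3–4 meals) inside the 80–120 mg/dL band for the large
majority of patient-minutes. The fast kernel peaks ~32 min post-intake, the
slow kernel ~90 min.

## Numerical integration

Integration is event-driven: the day is split at every meal onset, activity
start/stop, and each analytically predicted crossing of A through ATH
(within an activity segment A is linear in t, so the crossing time is exact).
Within a segment the branch flags are frozen and the smooth right-hand side
is integrated with adaptive LSODA (default rtol 1e-7, atol 1e-9); output is
resampled to a uniform 1-minute grid. This avoids solver chatter on the
discontinuous branches; a fixed-step RK4 reference integrator in the test
suite cross-validates the exercise-free reduction to the 3-state core.
Halving tolerances moves the worked-day glucose trace by far less than
0.1 mg/dL.

Degenerate situations: non-finite states raise immediately (integration
blow-up); a glucose trace driven non-positive is clamped at ε = 10⁻⁶ mg/dL
with a warning recorded in the result metadata; an initial state defaults
to the subject's rest equilibrium.

## Exercise lowers glucose — in what sense

Under the default parameters peripheral uptake outpaces hepatic production
(a3/a4 > a1/a2), and glycogen depletion only subtracts further, so exercise
is a net glucose-lowering input: during sustained activity the
with-exercise trace runs strictly below the no-exercise trace, and the
daily mean is lower with exercise for every simulated patient.

Pointwise domination over the whole day does **not** hold, and cannot: the
model is a closed loop. Exercise that lowers glucose during a post-meal
release ramp also suppresses insulin build-up, so the *next* meal's peak
can rebound above the no-exercise trace (about +9 mg/dL after dinner on the
worked day). This persists even with the insulin-removal channel removed,
i.e. it is a property of feedback regulation, not of a coefficient.
`exercise_contrast` therefore reports the pointwise difference and summary
deltas without asserting a sign on the peak reduction.

## The virtual population

Patients are drawn per sex × lifestyle group in dependency order: age,
height → BMI → weight = BMI·height² (the identity holds exactly by
construction) → basal glucose and daily carbohydrates → meal count.
Marginals are truncated normals at ±3 SD (a distribution family had to be
chosen; nothing heavier-tailed is implied by a mean ± SD table), with an
age floor of 20 y. The floor truncates age asymmetrically, so the age
sample mean follows the analytic truncated-normal mean rather than the raw
configured mean — the test suite checks it against that oracle. Basal
glucose, carbohydrates, height and BMI have symmetric truncation and
recover their configured means to Monte Carlo accuracy. A `bmi_slope` knob
shifts the glucose/carbohydrate means linearly per BMI z-score; its default
of 0 reproduces the configured marginals exactly. Resting heart rate is a
cohort-level marginal (75.4 ± 7.32 bpm); HRmax uses the classical
`220 − age` estimate, overridable per subject.

**Days.** 3 meals (breakfast/lunch/dinner) or 4 (plus an evening snack)
fall in fixed clock windows patterned on the worked day; the daily
carbohydrate total is Dirichlet-partitioned across meals, and each meal's
slow fraction is Beta(9, 1)-distributed toward slow absorption (three of
the four worked-day meals were slow-only). Five activities are placed
greedily, each starting within 3 h of some intake, anchors cycling over
meals; infeasible days are resampled wholesale. Active days are long walks
(115–150 min, 30–50 % HRmax) with at most one short run (25–45 min,
78 % HRmax), so scheduled activity always totals ≥ 8 h; sedentary days are
five 40–80 min blocks of desk work, reading or housework (10–27 % HRmax),
always totalling < 8 h. Consequently generated schedules classify back into
their own lifestyle group essentially always, and sedentary oxygen
consumption stays in the 8–30 % band.

**Two intensity traces.** Lifestyle classification integrates MET over the
*activity-only* trace (zero between activities, where MET(0) ≈ 1.32 < 1.5).
The *physiological* trace fed to the ODEs carries the 8 % basal between
activities; because the Gaussian MET fit maps 8 % to ≈ 1.9 MET, a
`GlycemicSummary.active_hours` computed on that trace saturates at 24 h —
a documented consequence of the fitted curve, which is steep at low
intensities and should not be read as a physical resting MET.

## What the synthetic machinery does not show

- Generated cohorts inherit only the group-level mean ± SD structure;
  real covariation (age–BMI, diet–activity) is absent unless `bmi_slope`
  is set, so passing tests validate the sampling machinery, not
  epidemiological realism.
- The female active group's basal-glucose spread (SD 7.35 mg/dL) places a
  tail of patients below 80 mg/dL at rest, so the 80–120 band-occupancy
  property is a statement about the active-men cohort, not every group.
- The model is limited to normal-weight, healthy physiology: no insulin
  dosing, no diabetic variants, no overweight correction, no stress or
  fatigue factors, and meals are a two-pool slow/fast split without
  glycemic-index structure. Intensity is piecewise-constant within an
  activity; ramping is out of scope. Multi-day simulation and closed-loop
  control are out of scope.
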