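# Methods

## The model

`hlsim` simulates a Hodgkin's-lymphoma-like tumor together with its
micro-environment as six interacting cell stocks:

* **CSC** — cancer stem cells: slow-dividing, self-renewing; the only
  compartment that can sustain the tumor on its own.
* **CTAC** — cancer transit amplifying cells: fast-dividing, fed by CSC
  differentiation, differentiating further into MTC.
* **MTC** — mature tumor cells (the Hodgkin/Reed–Sternberg analogue):
  non-proliferating by default, lost rapidly to natural death unless
  shielded.
* **Helper cells** — bystanders delivering anti-apoptotic "help" to all
  three tumor compartments and co-stimulation to killer cells.
* **Killer cells** — cytotoxic bystanders removing tumor cells at
  compartment-specific kill rates.
* **Regulatory cells** — bystanders suppressing helper and killer
  proliferation.

Each stock `S` follows a balance of a proliferation/increase flow and a
loss flow.  Proliferation is logistic-style, `max(0, g·S − c·S²)`, with
a per-compartment capacity constant `c` standing in for resource
limits; bystander proliferation is driven by a weighted sum of the
three tumor stocks (the "stimulation by tumor") and gated to zero when
the stimulation product is non-positive.  Losses have a common shape

    loss = max(0, death + killing − help) + differentiation + therapy·S

— helper cells can cancel death and killing inside the clamp but can
never turn a loss into a gain.  Killing of each tumor compartment is
proportional to the killer stock (not to the product of both
populations), so a large killer pool exerts a fixed per-day removal
pressure.

Therapies are rectangular pulses `PULSE(start, duration) · intensity`,
active on the half-open interval `[start, start+duration)`; one pulse
per compartment models cytotoxic therapy with compartment-specific
toxicity.  Negative intensities are allowed and model a transient
*increase* of the targeted compartment.  Two immunotherapy extensions
exist: an adoptive-transfer pulse adding killer cells at
`intensity` cells/day, and killing-amplification pulses multiplying the
killer attack on a chosen tumor compartment by `(1 + intensity)`.

## Integration

The discrete update rule is part of the model's definition, not a
numerical approximation to be improved on: fixed-step Euler with all
flows evaluated from the pre-step state and all six stocks advanced
simultaneously.  Each stock update passes through a non-negativity
guard — with per-day net rate `r`, the step is `S + dt·r` if
`S + r > 0` and `S + dt·(−S)` otherwise.  Two literal-minded
consequences are kept deliberately:

* the guard compares the stock against the **per-day** rate, not the
  dt-scaled increment;
* a fallback step leaves a small positive residue `S·(1−dt)` rather
  than clamping to exactly zero, so an "eliminated" stock decays
  geometrically into the subnormal range instead of reaching 0.0.

The default step is `dt = 2⁻⁷ = 0.0078125` days (the displayed value
0.007812 is a truncation of this power of two); states are recorded
every `saveper = 1` day, which the default step hits exactly.  Horizons
are 2000 days, or 4000 days for the killing-amplification experiments.
Default parameter values ship with the package (`docs/parameters.md`
maps the spelled-out names to canonical keys); notably MTC growth is a
real parameter that defaults to 0.

The production loop is numba-compiled (`hlsim._kernel`); a pure-Python
step (`hlsim.integrator.euler_step`) implements the identical
arithmetic and the test suite pins the two paths together step by step,
and pins both against an independent line-by-line transcription of the
published equation table on 1000 random states.

A property worth knowing: the guarded dynamics are effectively closed
under IEEE double arithmetic.  Every unbounded growth path runs through
a quadratic capacity term whose overflow poisons the `max(0, ·)` clamp
and shuts the flow off, so genuine non-finite states are exotic; the
integrator nevertheless checks every recorded state and reports the
first affected stock and save time.

## Outcome classification

`classify_outcome` reduces a trajectory of total tumor burden
(CSC + CTAC + MTC) to one of four labels:

* **eliminated** — final burden below `elimination_threshold`
  (default 0.5 cells, i.e. less than one cell);
* **relapse** — the burden fell below `relapse_low` (default 0.1) times
  its *running peak* (a deep, ≥90% response) and later exceeded
  `relapse_high` (default 10) times the initial burden;
* **suppressed** — final burden at most `control_ratio` (default 1)
  times the initial burden;
* **progression** — otherwise.

Remission is measured against the running peak rather than the initial
burden deliberately: therapy in these scenarios starts at day 400, when
the untreated burden has grown ~40-fold, so a therapy-induced collapse
from ~1200 to ~8 cells is a deep remission even though it never goes
below one tenth of the *initial* 30 cells.  Regrowth, by contrast, is
anchored to the initial burden, which keeps a post-remission plateau of
a few cells (stable remission) from being mislabeled as relapse.

The dynamics are strongly bistable — burdens either collapse toward
zero or regrow by orders of magnitude — so the labels are insensitive
to the exact threshold values; escape-window boundaries are
reproducible to ±2 days under criterion variation.

One regime needs a second signal.  Amplified CSC killing
(killing-amplification intensity ≥ 53) eradicates the stem-cell
compartment, after which the transit compartment drains, but a residual
mature-cell pool remains helper-shielded at a plateau (~3.5×10⁶ cells)
far above the initial burden.  This is the published notion of "stable
tumor control with elimination of cancer stem cells": the tumor can no
longer progress and the remainder is eliminable by a late cytotoxic
pulse.  The report therefore exposes `csc_eliminated` (final CSC below
the elimination threshold) and `controlled` (burden-suppressed *or*
CSC-eradicated); the amplification-threshold search uses `controlled`.
A burden-only criterion cannot see this regime at all.

## Experiments

* **Escape-window scan** (`scan_pulse_window`): for each integer start
  day, a single-day adoptive transfer of 10⁶ killer cells is applied
  and the run classified; the scan reports the contiguous runs of
  non-suppressed start days.  With defaults over days 1–300 the failure
  window is days 202–243 and suppression holds again through day 291
  before failing permanently — early transfer kills the tumor while
  the initially shrinking CTAC/MTC pools still under-stimulate the
  immune compartments; with initial CTAC = MTC = 0 the window
  disappears.
* **Dose-timing boundary**: a 1.5×10¹⁰-cell single-day pulse eliminates
  the tumor when given at day 300 or 301 but not at day 302 (a
  two-day pulse still succeeds there).
* **Minimal-dose search** (`find_min_intensity`): decade scan then
  geometric bisection to ~2 significant figures, assuming (and
  verifying at the bracket ends) monotone outcome in the dose.  With
  defaults the minimal suppressing dose is ≈3×10¹² cells at day 500,
  ≈2×10¹⁴ at day 1000 and ≈7×10¹⁵ at day 1500.
* **Amplification threshold** (`find_threshold_integer`): ascending
  integer scan of a killing-amplification intensity; the smallest
  CSC-only amplification achieving control is 53 (52 fails), at both
  dt = 2⁻⁷ and dt = 0.007812.  MTC-only amplification never controls
  the tumor at any intensity.

## Numerical sensitivity of the paradox-enhancement regime

At the control threshold the system rides a knife edge: the ratio of
killer attack on CSC to helper shielding sits at ≈0.993 for more than a
thousand simulated days before tipping to elimination or escape.
Outcomes in this regime are genuinely non-robust: they flip under step
perturbation (2⁻⁷ vs 0.007812 vs 2⁻⁸) and under sub-percent dose
perturbation.  Concretely, with the default step the
all-three-compartments amplification (53/53/53) eliminates the tumor,
while at the displayed step 0.007812 it escapes (the paradox:
amplifying CTAC/MTC killing removes the killer-stimulating tumor mass
and destabilizes control).  The package therefore runs the
paradox-differential tests at the displayed step, where the paradox and
its rescues by helper depletion or a killer-toxicity pulse all
reproduce; the rescue by an adoptive transfer of exactly 3.5×10¹⁰ cells
at day 1000 does *not* reproduce there (neighboring doses 10¹⁰ and
10¹¹ both rescue), and the corresponding test is left failing rather
than tuned.  Robust quantities — window boundaries, timing boundary,
dose bounds, the threshold 53, all scenario labels outside this regime —
are stable under dt halving (tumor stocks converge to <0.5%; the
killer compartment shows a transient step-sensitivity of its
proliferation switch-on time, which is why convergence is asserted on
the tumor compartments and on labels).

## Scenario presets

Every published simulation ships as a named preset in a human-readable
YAML manifest (`hlsim/data/scenarios.yaml`), fully resolved (no
"same as previous figure" chains).  Presets whose source leaves a knob
unstated (the adoptive-transfer start day of the timing figures, the
amplification combinations of the combination figure) declare it as a
required override instead of guessing; the killer-toxicity rescue
preset uses intensity 0.9 for its "short toxic pulse", a package
choice.

## Problem sizes

The shipped experiments use the study's own scales: 2000- or 4000-day
horizons at dt = 2⁻⁷ (256k/512k Euler steps per run), a 300-day window
scan (300 runs), ≈20-run dose searches per time point and a ≤100-run
threshold scan.  The full test suite performs ~500 simulations.

## Limitations

No spatial structure, no stochastic kinetics, no pharmacokinetics, no
cell types beyond the six stocks; killing pressure independent of
tumor-cell density and near-immortal effector cells (death rate
10⁻⁵/day) are inherited modeling idealizations.  Conclusions inside the
knife-edge regime describe this discrete model at a stated step size,
not a step-converged continuous system.
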