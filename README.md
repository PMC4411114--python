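# hlsim

Simulator of Hodgkin's lymphoma tumor–microenvironment dynamics: a
stock-and-flow model of six interacting cell populations — cancer stem
cells (CSC), cancer transit amplifying cells (CTAC) and mature tumor
cells (MTC), plus helper, killer and regulatory bystander cells — with
pulse cytotoxic therapies and two immunotherapy extensions (adoptive
killer-cell transfer and killing-amplification).  It is written for
modelers and translational researchers who want to explore how
tumor–stroma feedback shapes therapy outcomes: relapse after
insufficient stem-cell targeting, immune-escape windows for adoptive
transfer, and paradoxical tumor enhancement after treatment.

## Model

Each stock `S` obeys a clamped balance of flows, advanced by fixed-step
Euler integration (the update rule is part of the model definition):

    S(t+Δt) = S(t) + Δt · r,   r = gain − loss,  replaced by −S(t) if S(t) + r ≤ 0

with logistic-style proliferation `max(0, g·S − c·S²)` against a
capacity `c`, and losses of the form

    loss = max(0, death + killing − help) + differentiation + therapy·S

Tumor cells stimulate all three bystander compartments; helper cells
shield tumor cells inside the loss clamp and co-stimulate killers;
regulatory cells suppress helper and killer proliferation; killers
remove tumor cells at compartment-specific rates, optionally amplified
by `(1 + ImmunoTHx2)` during a vaccination-like pulse, while
`ImmunoTHx1` adds killer cells directly (adoptive transfer).  All
therapies are rectangular pulses `PULSE(start, dur) · intensity`,
active on `[start, start + dur)`.  Defaults (see
`docs/parameters.md`) give massive tumor growth over 2000 days;
Δt = 2⁻⁷ days, sampled daily.  `docs/methods.md` has the full account.

## Worked example

Reproduce the relapse-after-insufficient-stem-cell-targeting scenario
(intense therapy against MTC/CTAC, weak against CSC, starting day 400):

```text
$ hlsim run --scenario fig7_relapse --out fig7.csv
outcome:        relapse
initial burden: 30 cells
final burden:   9.92653e+06 cells
minimum burden: 7.98366 cells at day 500
CSC eliminated: no
regrowth after day 682
```

The tumor collapses ~150-fold during the 100-day therapy pulse but the
surviving stem cells re-seed it: by day 682 the burden has regrown past
ten times its initial value, reaching ~10⁷ cells at day 2000.
Lowering the therapy's toxicity for regulatory cells instead yields
stable remission:

```text
$ hlsim run --scenario fig10_remission
outcome:        suppressed
initial burden: 30 cells
final burden:   5.12266 cells
minimum burden: 0.536393 cells at day 600
CSC eliminated: no
```

and the just-sufficient stem-cell-killing amplification can be searched
directly:

```text
$ hlsim find-threshold --field immuno2_csc_intens --lo 50 --hi 60
smallest controlling immuno2_csc_intens: 53
```

`hlsim list-scenarios` shows every preset (all main and supplementary
simulations); the same operations are available from Python:

```python
from hlsim import get_scenario, simulate, classify_outcome
params, settings = get_scenario("fig7_relapse")
report = classify_outcome(simulate(params, settings))
print(report.label, report.final_burden)   # relapse 9926533.58...
```

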