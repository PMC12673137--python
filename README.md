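# phenoswitch

Compartmental phenotypic-switch models of drug-tolerant persister
dynamics in clonal cancer cell populations, for researchers studying
fractional killing and treatment scheduling of pro-apoptotic
(TRAIL-like) and pro-necroptotic (TBQ-like) drugs.

Cancer cells surviving a lethal drug exposure often do so through a
transient, non-genetic tolerant state rather than mutation. This
package models a dish of isogenic cells as drug-sensitivity
compartments exchanging density through phenotypic switching, with the
drug acting through impulsive kills and lingering "memory" effects:

```
dS/dt = P(N)·S − α_ST·S + α_TS·T          N = S + T  (% dish area)
dT/dt = P(N)·T + α_ST·S − α_TS·T
dM/dt = μ·D/(D + D50) − λ·M               one memory per modulated rate
```

- `P(N)` — per-capita proliferation, by default the saturating Hill
  law `β(1 − (N/N_max)^n)` with `N_max = 100 %`;
- at each drug input the sensitive compartment is removed
  (`S ← κ·S`, `κ = 0`) and the dish concentration is reset, then
  decays piecewise linearly at `k_d`;
- a *topology* — one of 8 on/off hypotheses — decides whether the drug
  (through its memories) activates `α_ST`, inhibits `α_TS`, and/or
  inhibits `β`;
- the drug-free population settles at the equilibrium
  `(S_eq, T_eq) = 100·(α_TS, α_ST)/(α_ST + α_TS)` at rate
  `α_ST + α_TS`.

A coupled two-drug model (three compartments `S_A`, `S_N`, `T`) adds
apoptosis-induced sensitization to necroptosis: drug A activates the
`T → S_N` switch through a dedicated memory, which is what makes
*alternating* the two cell-death modalities more effective than
repeating either drug.

The package covers simulation (adaptive and compiled fixed-step
engines with exact impulse handling), growth-law selection by mean
AIC, penalized least-squares calibration per topology with RMSE
topology grids, coupling estimation, equilibrium/relaxation/growth-
decomposition analytics, and seeded synthetic data generators that
stand in for wet-lab density measurements.

## Worked example

Contrast 30 days of daily repeated apoptotic treatment with daily
alternation of the apoptotic and necroptotic drugs
(`examples/04_alternating_therapy.py`):

```python
import numpy as np
import phenoswitch as ps

params = ps.default_params_2d()          # synthetic reference parameter set
rep = ps.repeated(ps.DrugId.A, 20.0, n_inputs=30, horizon=720.0)
alt = ps.alternated(20.0, 10.0, n_inputs=30, horizon=720.0)

for name, sched in [("Repeated A", rep), ("Alternated A/N", alt)]:
    traj = ps.simulate_psm2d(params, sched)
    n = traj.sample_N(np.arange(0.0, 721.0, 96.0), side="left")
    print(name, np.round(n, 2))
    print(ps.detect_threshold_crossing(traj, occupation_threshold=95.0))
```

prints

```
Repeated A [10.   55.44 96.88 98.57 98.64 98.66 98.66 98.66]
CrossingReport(extinction_time=None, occupation_time=180.85073455244168, extinction_threshold=0.1, occupation_threshold=95.0)
Alternated A/N [10.    0.52  0.04  0.    0.    0.    0.    0.  ]
CrossingReport(extinction_time=120.0, occupation_time=None, extinction_threshold=0.1, occupation_threshold=95.0)
```

Under repeated apoptotic dosing the necroptosis-sensitive cells hiding
inside the apoptosis-tolerant pool regrow the dish to a near-full
plateau (past 95 % by day 7.5); alternating the modalities drives the
population below the 0.1 % extinction threshold by day 5 and keeps it
there. The other example scripts walk through regimen simulation,
growth-law selection, topology discrimination, and equilibrium/memory
analytics — each prints the numbers it computes and a line on what
they mean.

## Layout

- `src/phenoswitch/` — library: `model` (PSM1D), `psm2d`, `calibration`,
  `analysis`, `synthetic`, `regimens`, `trajectory`, `io`, `reference`
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite including the validation tests
- `docs/methods.md` — model equations, parameter defaults, numerical
  choices and limitations
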