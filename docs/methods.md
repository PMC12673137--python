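# Methods

`phenoswitch` implements deterministic, impulsive compartmental models
of drug-sensitivity phenotypic switching in a clonal cancer cell
population growing in a dish, together with the calibration and
benchmarking machinery around them. This note records the model
equations, the meaning and defaults of every tunable parameter, the
numerical choices, what the synthetic data emulate, and the design
decisions taken where more than one reasonable construction existed.

## The one-drug model (PSM1D)

The population is split into a drug-sensitive compartment `S` and a
drug-tolerant compartment `T`, both measured in percent of dish area
occupied; `N = S + T`. Between drug inputs the dynamics are smooth:

```
dS/dt = P(N) S  -  a_ST S  +  a_TS T
dT/dt = P(N) T  +  a_ST S  -  a_TS T
```

Daughter cells inherit their mother's phenotype, so each compartment's
share of the global proliferation `P(N)·N` is its own density share —
which reduces the renewal term to `P(N)·S` (and `P(N)·T`). Switching
moves density between compartments without creating or destroying it:
`dN/dt = P(N)·N` exactly, an identity the test suite asserts along
simulated trajectories. An empty dish (`N = 0`) is absorbing: the
compartment derivatives are set to zero there.

**Proliferation.** Four candidate per-capita laws are implemented
(`beta` in 1/h, `N_max = 100 %` dish area):

| law | `P(N)` | notes |
|---|---|---|
| exponential | `beta` | unbounded; control fits only |
| logistic | `beta (1 - N/N_max)` | |
| gompertz | `beta ln(N_max/N)` | rate capped at `N = 1e-3 %` to avoid the log singularity |
| hill (default) | `beta (1 - (N/N_max)^n)` | generalized logistic; saturates exactly at `N_max` |

The Hill law is written in this saturating polynomial form because the
shape parameter `n` must sharpen the approach to confluence while
keeping `P(N_max) = 0`; a rational variant `beta / (1 + (N/N_max)^n)`
(which does *not* vanish at `N_max`) is available behind the
`hill_rational` switch for sensitivity analysis.

**Drug concentration.** Each drug input at time `t_d` sets the dish
concentration to the administered dose; between inputs it decays
piecewise linearly at rate `k_d` (dose/h), floored at zero. A *wash*
(medium replacement) zeroes all drugs before the new dose is applied,
so a wash + treat event is a reset, not an addition; the Sustained
regimen has a single input and no reset. `D(t)` is evaluated in closed
form rather than integrated, so it is exact.

**Impulsive death.** A drug input instantaneously removes the
sensitive compartment: `S <- kappa·S` with surviving fraction
`kappa = 0` by default (`kappa` is kept as a parameter for sensitivity
analysis). `T`, the memories, and — across the kill itself — the drug
variables of other drugs are continuous.

**Memory variables.** The drug does not act on rates directly; each
modulated rate carries a memory `M` of retained drug effect:

```
dM/dt = mu · D/(D + D_50)  -  lambda · M
```

`mu` (1/h) is the sensitivity to drug stress, `lambda` (1/h) the reset
speed, and the Emax-type saturation `D/(D + D_50)` bounds the input
(`D_50` defaults to the experimental dose). At constant `D` the memory
relaxes to `(mu/lambda) · D/(D + D_50)`.

**Topologies.** A drug may (i) activate the S→T switch, (ii) inhibit
the T→S switch, (iii) inhibit proliferation — eight on/off
combinations. Activation multiplies a rate by `(1 + M)`, inhibition
divides by `(1 + M)`: both are positive, monotone and the identity at
`M = 0`. The package numbers the eight variants with an explicit
canonical table (`TOPOLOGY_TABLE`); indices 2 `(+,=,-)` and 3 `(+,-,-)`
hold the variants best supported for the necroptotic and apoptotic
treatments respectively. The numbering is a package convention — the
flags, not the index, define the model.

**Drug-free equilibrium.** The sensitive *fraction* `s = S/N` obeys
`ds/dt = a_TS - (a_TS + a_ST) s` independently of the growth law, so
the population relaxes exponentially at rate `a_ST + a_TS` to

```
(S_eq, T_eq) = 100 · (a_TS, a_ST) / (a_ST + a_TS)   [% of population]
```

This closed form, its relaxation timing `ln(d0/eps)/(a_ST + a_TS)`, and
its invariance to `beta` and `n` are all verified numerically by the
validation suite. "Time to equilibrium" of a treated trajectory is
measured from the last drug input (the reset delay) as the first entry
into a band of ±1 % (absolute, in population percent) around `S_eq`
that is never left again; the band width is configurable.

## The two-drug model (PSM2D)

Two one-drug models — drug A (pro-apoptotic, TRAIL-like) and drug N
(pro-necroptotic, TBQ-like) — are coupled into three compartments:
`S_A`, `S_N` and a doubly tolerant `T`. All switching traffic routes
through `T` (no direct `S_A <-> S_N` transitions), the per-capita
proliferation is shared at the total density, and each drug's
concentration and memories evolve independently. Proliferation
inhibitions from the two drugs compose multiplicatively.

The coupling implements apoptosis-induced sensitization to necroptosis:
drug A charges a dedicated memory `M_TSN` (parameters `mu_TSN`,
`lambda_TSN`) that activates the `T -> S_N` rate as
`a_TSN0 · (1 + M_TSN)`. With a fast reset (`lambda_TSN` large) the
activated rate simply tracks the drug-A concentration — the default
regime, in which the sensitization carries no long-term memory.

**Kill sets.** Drug A removes `S_A`. Drug N removes both `S_N` and
`S_A`, because the necroptotic combination contains the apoptotic
ligand; the mapping is configurable (`kill_sets=`) since the survival
of `S_A` under the combination is not experimentally settled.

**No bistability.** With memories at zero the proportion dynamics are
linear with a single attracting fixed point (the stationary
distribution of the switching generator). The suite verifies the
absence of hysteresis numerically: 50 random initial proportion
vectors converge to the same proportions within 1e-4.

**Thresholds.** Long-horizon outcomes are summarized by the first
crossing of an extinction threshold (default 0.1 % dish area) and an
occupation threshold (default 99.5 %); neither value is canonical and
both are arguments.

## Simulation engine

Integration proceeds on half-open intervals between events; the
impulse (kill + drug reset) is applied at each event time and
integration restarts from the right limit. Trajectories store both
limits at impulse times; sampling at a dosing time returns the
pre-treatment (left) state by default, matching a dish measured just
before wash + treat. Because `D(t)` is closed-form, each interval is
additionally split where the linear decay reaches zero so the solver
only ever sees a smooth right-hand side.

Two integration paths share the same compiled right-hand side:

- `method="adaptive"` (default): `scipy.integrate.solve_ivp` RK45 at
  `rtol = 1e-8`, `atol = 1e-10`;
- `method="fixed"`: a compiled fixed-step RK4 kernel (default step
  0.05 h; calibration uses 0.1 h), roughly three orders of magnitude
  faster, used inside calibration loops.

An independent pure-Python RK4 replay (`reference_states_psm1d`, its
own right-hand-side algebra) cross-checks both: at `dt = 1e-3 h` the
two routes agree to ~1e-8 % area over 72 h, far inside the 1e-3
acceptance band. Post-simulation invariant checks reject states below
−1e-9 or total density more than 1e-6 above capacity; solver-level
noise below those tolerances is clamped, not propagated.

## Calibration

**Growth law first.** The proliferation parameters are fitted on
no-drug control curves at several seeding densities, in two regimes:
one shared `theta` for all seedings, and one `theta` per seeding.
Candidates are ranked by mean AIC across seedings, in the
least-squares form `AIC = m ln(RSS/m) + 2k` (the mean is arithmetic).
Model identification among the four laws uses the shared regime — with
nested candidates (logistic ⊂ Hill) the per-seeding regime gives the
larger model several independent chances to absorb noise, while the
shared regime's single χ² fluctuation almost never overcomes the 2k
penalty. The per-seeding regime is what demonstrates density-dependent
growth adaptation, and its fits provide the parameters used downstream.

**Observation model.** Regimen datasets are long-format records
`(time_h, regimen, replicate, density_pct, seeding_pct, compartment)`.
The `compartment` column tags what a row measures: total density `N`,
or the resolved `S`/`T` split — treatment experiments resolve it
because the density drop caused by the next drug input separates the
killed (sensitive) from the surviving (tolerant) part of the dish.
Compartment-resolved observations are the generator default and matter:
with `N`-only 24-h observations several topologies are structurally
non-identifiable (distinct parameter sets reproduce every observation
to ~1e-6 % area), whereas with `S`/`T` rows all eight topologies are
exactly identifiable at zero noise. Goodness of fit is nevertheless
always *reported* as the RMSE of the total density `N` on the 24-h
grid, computed against the replicate-mean curve.

**Cost and optimizer.** One parameter vector is shared by all regimens
of a dataset. The cost is the weighted sum of squared residuals
(weights per regimen, default 1) plus a quadratic exterior penalty on
bound violations. Free parameters per topology: the two switching
baselines; the drug decay `k_d` when any effect is active; and
`(mu, lambda)` for each active effect. The input dose is *fixed* at
the experimental value by default: it enters the dynamics only through
the saturating memory input, where it is confounded with the memory
sensitivities, and it is known experimentally; `calibrate_dose=True`
frees it within ±50 % of the dose. All free parameters are positive
rates spanning decades, so the search runs in log space: multi-start
trust-region least squares on the residual vector (SciPy TRF, two
passes per start), with starts beyond the supplied initial guess drawn
log-uniformly between the bounds from a seeded generator, stopping
early once a start reaches cost 1e-12. Scalar derivative-free Powell
search is retained as `optimizer="powell"`; in head-to-head runs it
stalls on the sloppy valleys of the richer topologies where the
residual-vector solver reaches the global basin in seconds.
Simulation failures inside the cost yield a large finite sentinel so
optimization continues. Every calibration is bit-reproducible given
its seed.

Default bounds and initial guesses (chosen from the orders of magnitude
a dish experiment admits, not from any fit): switching baselines
1e-4–0.5 /h, guess 0.02; `k_d` 0.01–5 dose/h, guess dose/24 (drug
roughly cleared within a day); `mu` 1e-4–1 /h, guess 0.05; `lambda`
1e-3–1 /h, guess 0.02. The initial compartment split is the candidate
parameters' own equilibrium at the dataset's t = 0 density.

**Topology grid.** Every topology is calibrated once on all regimens
combined; the grid holds the per-regimen RMSE of that fit (8 × 3 for
the standard regimen set), with the per-regimen argmin and a min-max
scaling across all cells for heatmap display. Failed calibrations
become missing cells rather than aborting the grid.

**Coupling.** With the one-drug fits frozen, `(mu_TSN, lambda_TSN)`
are fitted on alternated-regimen total densities by the same
multi-start residual solver (bounds 1e-3–10 and 1e-3–2 /h). Two
parameters against a multi-day density curve are well identified; the
zero-noise benchmark recovers them to machine precision.

## Synthetic data

The generators emulate clonogenicity-style density measurements:
fractions of dish area on a 24-h grid, a few replicates, sigmoidal
saturation toward 100 %, post-treatment drops of the sensitive
compartment. Observation noise is additive Gaussian with
`sigma = 1 %` dish area, truncated at 0 and clamped at 100 (a
multiplicative lognormal model is available); the scale reflects the
replicate scatter typical of plate densitometry. Every dataset carries
a provenance block (true parameters, topology, noise, seed).

The reference ground-truth parameter sets are *synthetic* — they stand
in for calibrated values that are not part of this package's inputs —
and were fixed once from domain reasoning: dish-level Hill growth at
`beta = 0.04 /h`, `n = 2` (low-density doubling ≈ 17 h); a naive
equilibrium of 80 % sensitive / 20 % tolerant relaxing on a ~3-day
timescale (`a_ST0 = 0.01`, `a_TS0 = 0.04 /h`); doses 20 (drug A) and
10 (drug N) with `D_50` at the dose and `k_d` clearing the dish in
about a day; memory charge rates 0.03–0.05 /h with resets of 1–2 days
for drug A, slower (0.005 /h) for drug N whose effects are the more
persistent; topology 3 `(+,-,-)` for drug A and 2 `(+,=,-)` for drug
N; and a fast-reset coupling (`mu_TSN = 2.5`, `lambda_TSN = 0.5 /h`)
so the sensitization tracks the apoptotic drug. Initial density is
10 % of the dish split at the naive equilibrium.

What passing the synthetic benchmarks shows — and what it does not:
exact recovery at zero noise demonstrates the estimator and the
identifiability of the *compartment-resolved* design, and the noisy
benchmark shows the rate *ratio* (hence the equilibrium proportions)
survives 1 %-area replicate noise. It does not show that real dishes
satisfy the model's assumptions (perfect phenotype inheritance, well-
mixed exposure, complete kill of the sensitive pool), nor that real
replicate noise is additive and homoscedastic.

## Long-horizon regimen contrast

With the synthetic reference set, 30 days of daily A/N alternation
extinguishes the population (below 0.1 % within the first week) while
30 days of repeated drug A lets the dish fill to a plateau just below
capacity (~98.7 %, necroptosis-sensitive cells dominating), crossing
95 % within about a week; the alternated dish stays below 5 % from
day 2 onward; a treated population needs well over three drug-free
days to regain its naive equilibrium, and longer after repeated dosing
than after a schedule containing a holiday. These directional
statements are asserted by the validation suite; the exact day counts
depend on the synthetic parameter choices and are reported, not
asserted, by `scripts/acceptance.py`.

## Numerical conventions and edge cases

- Hours everywhere; schedule files may give days (`time_day` column),
  converted on read.
- Observations at a dosing time are left limits; `Trajectory.sample`
  exposes both sides.
- Event times must be strictly increasing and within the horizon; an
  event exactly at the horizon is applied after integration ends.
- `aic` returns −inf with a warning at RSS = 0 (perfect fit).
- Equilibrium proportions are undefined when both switching rates are
  zero (error); `time_to_equilibrium` returns `None` when the band is
  never entered or never held.
- Threshold crossings interpolate linearly between samples; a jump at
  an impulse crosses exactly at the impulse time.
- Fit problem sizes in the shipped benchmarks (three regimens of a
  7-day horizon sampled daily, one to three replicates; 2–3 optimizer
  starts) were chosen so a full 8-topology recovery sweep plus the
  topology grid completes in a couple of minutes on one core, while
  remaining comfortably inside the regime where the estimator is
  exact at zero noise.

## Known limitations

- Deterministic population model: no demographic stochasticity, so
  "extinction" means crossing a small density threshold, not loss of
  the last cell.
- Drug pharmacology is deliberately minimal (linear decay, saturating
  memory input); no intracellular signaling.
- The formal stability analysis of the equilibria is replaced by
  numerical convergence checks.
- The N-only observation design is supported but leaves the richer
  topologies practically non-identifiable; compartment-resolved data
  (or informative priors) are required for full parameter recovery.
- No Bayesian uncertainty quantification; calibrations are point fits
  with multi-start diagnostics.
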