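# Methods

## Model overview and assumptions

The package predicts dissolved oxygen (DO) inside a single cylindrical
sea cage from four ingredients: oxygen solubility of the ambient water,
the swimming energetics of the stocked fish, a hypoxia ceiling on their
aerobic metabolism, and plug-flow water exchange. The governing
simplifications are deliberate and shared by all three calculation
series:

* fish are distributed uniformly at the stocking density ρ, so volumetric
  uptake is `MO2·ρ` (mg O2 m⁻³ h⁻¹; divided by 1000 for mg L⁻¹ — this
  unit bridge is applied everywhere);
* water moves through the cage as plug flow with no mixing, re-aeration,
  vertical structure, or interaction with neighbouring cages;
* all fish swim at the same speed — at rest, at the preferred speed
  `Upref = 1.1 BL s⁻¹`, or matching the current — and fed fish carry a
  specific dynamic action (SDA) surcharge equal to 40% of SMR,
  independent of temperature and speed;
* behavioural aggregation (e.g., crowding at feeding) is not modelled,
  so predictions are a best case: real cages are patchier and locally
  worse.

Because fish distribution is uniform, CS1 (still water, time t), CS2
(fixed current, distance x at travel time x/v) and CS3 (current sweep)
are the same ordinary differential equation with different clocks:

    dC/dt = − uptake(C) · ρ / 1000        [mg L⁻¹ h⁻¹]

with `uptake(C)` the Hill-capped demand at the current concentration.

## Swimming energetics

MO2 versus speed is exponential, `MO2 = a·e^{bU}`, fitted as a linear
regression of ln MO2 on U. The log-space fit is closed-form and
deterministic and matches the multiplicative error structure of
respirometry; a nonlinear least-squares refinement is available as a
sensitivity option (`fit_swim_curve(..., nonlinear=True)`). The
intercept `a` is the SMR; `Uopt = 1/b` minimizes cost of transport
`MO2/U`; Brett's formula gives Ucrit from incremental trials. Rates are
mass-adjusted to 1.5 kg with exponent A = 0.89 (rainbow trout); Q10
quantifies temperature scaling. The SDA surcharge is additive on SMR
(`+ 0.40·a` when fed), not multiplicative on swimming MO2: the
equilibrium feeding experiments express the surcharge as a fraction of
the baseline rate, and digestion load does not grow with speed.

## Hypoxia ceiling

The maximum aerobic rate under hypoxia is
`ceiling(pO2) = AMR / (1 + (P50/pO2)^c)` with AMR fixed from normoxia
trials. P50 and c are fitted by least squares with points required to
bracket AMR/2, else the sigmoid is underdetermined. The closed-form
inverse gives the minimum pO2 for any target rate (Pcrit at a speed is
the inverse evaluated at that speed's demand). The Hill constants are
treated as kPa pO2 quantities; conversions to and from concentration go
through the solubility module.

When demand exceeds the ceiling, the fish slows: total uptake equals the
ceiling, the obligatory SDA share is paid first, and swimming receives
the remainder (`U = ln((ceiling − SDA)/a)/b`, clamped to
[0, desired]). Digestion-first priority is a modelling choice —
digestion of an ingested meal is not voluntary, swimming speed is. If
the ceiling cannot cover even maintenance (SMR + SDA), speed is zero and
the state is flagged below-maintenance; uptake still equals the ceiling,
never more.

## Solubility and units

Air-equilibrium O2 concentration uses the Garcia–Gordon refit of the
Benson–Krause data (combined temperature–salinity equation, mL L⁻¹
coefficients × 1.42905), with barometric pressure applied through the
moist-air factor `(P − p_w)/(P₀ − p_w)` and water vapor pressure from
the Buck equation. Air's O2 mole fraction is fixed at 0.2095;
1 atm = 101.325 kPa. `WaterConditions` accepts an explicit solubility
override so published solubility values can be injected verbatim; the
bundled case study does exactly that (9.39/8.44/7.63 mg L⁻¹ at
10/15/20 °C), which keeps cage-model verification independent of the
solubility-formula choice. The computed values (9.32/8.38/7.61) sit
within 0.1 mg L⁻¹ of those references. Valid ranges: −2…40 °C,
0…40 ppt, pressure > 0. Depth (hydrostatic) corrections, supersaturation
kinetics and carbonate chemistry are out of scope.

## Calculation series: numerics

CS1 integrates the depletion ODE by forward Euler at dt = 1 s (the
linear phase is exact at any step; the capped tail converges — dt = 1 s
and dt = 0.1 s agree within 0.1% at the crossings, and the closed-form
linear-phase crossing agrees within 0.5%). Crossing times for the DO
threshold are reported both continuously (linear interpolation inside
the step) and floored to whole minutes for table-style presentation.
Under the Hill cap, true anoxia is asymptotic (uptake → 0 as pO2 → 0),
so "anoxia" is operationalized as 1% of air saturation and reported as
not-reached when the horizon ends first. The default horizon is 24 h.

CS2 reuses the same integrator with distance = velocity × time,
profiling [0, diameter] in 2000 steps and continuing past the
downstream edge (up to 50 diameters) to locate the largest cage whose
downstream edge still meets the threshold. CS3 evaluates the
downstream-edge concentration over a velocity grid (default 0.5–20
cm s⁻¹ in 0.5 steps) under two swim policies — speed matching the
current, or Upref with a floor (`max(Upref, v/length)`) — taking a
closed-form shortcut whenever the ceiling stays slack over the whole
transect, and refines the minimum compliant flow by bisection to
0.01 cm s⁻¹. BL s⁻¹ ↔ cm s⁻¹ conversion uses the mean fish length once,
at the scenario boundary.

The feed-utilization threshold is the published salmonid regression
`%DO = 2.875·T + 22.85`, clamped to at most 100%, refittable from
(temperature, %DO) points by ordinary least squares.

## Respirometry analysis

Measure-phase MO2 is `−slope × 3600 × (V − m)/m` with the O2 slope from
a full-phase linear regression (mg L⁻¹ s⁻¹), chamber volume V in litres
and fish mass m in kg; fish displacement is approximated as 1 L kg⁻¹,
the standard respirometry convention. Phase-edge trimming is not
applied. An optional blank channel subtracts background respiration;
the correction defaults off because a cleaned system's background is
negligible. Rising-O2 phases are rejected rather than returned as
negative rates.

RMR is the median of night-window (default 19:00–07:00, matching a
12:12 photoperiod) measurements preceding the first feeding. The SDA
equilibrium under daily feeding is detected on daily means: the first
run of ≥ 3 consecutive days agreeing pairwise within 5% (relative),
extended while agreement holds; the plateau is the mean over the run.
The window length and tolerance are this package's operationalization of
what is usually judged by eye; both are parameters.

## Synthetic data generators

All generators derive every draw from one integer seed, so outputs are
byte-identical under a fixed seed. Defaults mirror the laboratory
designs the analysis routines target: increments from 0.4 BL s⁻¹ in 0.3
steps of 25 min (10 fish, per-fish target Ucrit ~ N(2.0, 0.25)); a 40-min
open-tank cycle with one daily meal of 1% body mass from day 2 (no feed
in the first 24 h) over 17 days with feeding halted after day 11;
measurement noise as mean-one lognormal with CV 0.03, typical of
optode-based slope estimates (tests that probe noisier regimes pass 5%
explicitly).

The hypoxia generator integrates a closed 90 L swim-tunnel with the fish
at a fixed speed, uptake `min(demand, ceiling)`, until uptake collapses
to 5% of demand. The default speed (2.0 BL s⁻¹) is chosen so demand sits
well above AMR/2: the self-induced decline then traverses the sigmoid's
inflection, which the Hill refit requires of a single trace. (The
laboratory protocol instead combines several speeds plus the normoxia
AMR anchor.) Reconstructing (pO2, MO2) pairs by adjacent-sample forward
differences with left-endpoint pO2 exactly inverts the generator's Euler
scheme, so noiseless traces refit to machine precision; noisy traces use
windowed slopes, and points still on the uncapped demand plateau are
excluded from the fit because they do not lie on the Hill curve.

The SDA kernel is a lagged Erlang density (shape 4, 6 h onset lag,
scale set so 95% of the mass falls within 50 h after the lag — the
single-meal response duration reported for rainbow trout at 10 °C),
scaled so the equilibrium daily mean is `RMR × (1 + target fraction)`.
The shape was chosen over a broader shape-2 gamma so that, under daily
meals, the plateau emerges cleanly around day 4–6 with the early rise
days clearly below it, as the feeding experiments show. Daytime activity
excursions (half-sine bumps) are available but default off; the
night-median RMR estimator is robust to them either way. What the
generators deliberately do not emulate: inter-individual variance
structure beyond lognormal noise, gait transitions near Ucrit, EPOC
after hypoxia, tank gas exchange (measured nil), and meal-size dynamics
— so passing recovery tests demonstrates correctness of the estimators
under the stated error model, not robustness to every field artefact.

## Reference reproduction and known discrepancies

With the published case-study constants, the package reproduces exactly:
cage volume/diameter (16,297.5 m³, 50.9 m), the threshold regression
(2.875, 22.85), DO thresholds at 15/20 °C (5.57/6.13 mg L⁻¹), the 15 °C
CS1 crossing (36 min floored), the 10 °C CS2 downstream edge
(7.9 mg L⁻¹), Uopt at 15 °C (1.1 BL s⁻¹), the 1.5-kg mass adjustment
(53.1 → 54.8) and the SMR Q10 values (2.0 measured, 1.8 adjusted).

A direct reading of the printed equations does **not** recover several
other published cells; the package follows the equations and reports its
own values rather than fitting to the published ones: CS1 crossings at
10/20 °C compute to 52.3/14.8 min (published 58/19), CS2 downstream
edges at 15/20 °C to 7.11/5.91 mg L⁻¹ (published 6.9/6.1), maximum cage
diameters to 156.9/109.6/44.4 m (published 155.7/98.0/29.6), and CS3
minimum flows to 1.63/2.32/5.73 cm s⁻¹ (published 1.5/2.2/5.6). The
`case-study` command flags these cells in its log. One downstream
consequence: the recomputed 10 → 20 °C CS1 speed-up is ×3.53 and the
CS3 flow ratio ×3.53, versus ×3.05 and ×3.73 implied by the published
table.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `upref` | 1.1 | BL s⁻¹ | preferred swimming speed, all temperatures |
| `sda_fraction` | 0.40 | — | fed surcharge as a fraction of SMR |
| mass exponent `A` | 0.89 | — | allometric scaling of MO2 |
| target mass | 1.5 | kg | common mass for rate comparison |
| threshold line | 2.875·T + 22.85 | %DO | feed-utilization limit |
| `dt` (CS1) | 1.0 | s | Euler step |
| CS3 refinement | 0.01 | cm s⁻¹ | bisection tolerance on minimum flow |
| anoxia level | 1% | of saturation | operational anoxia definition |
| night window | 19–07 | clock h | RMR baseline window |
| plateau window/tol | 3 d / 5% | — | SDA equilibrium detection |

## Limitations

Single cage, uniform fish distribution, no vertical DO structure, no
re-aeration or inter-cage transport; SDA is a constant fraction of SMR
rather than a mechanistic digestion model; anaerobic metabolism and
oxygen debt are not modelled, so behaviour near and below Pcrit is a
ceiling argument, not a survival prediction; the solubility formula is
one of several near-equivalent standards (hence the override).
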