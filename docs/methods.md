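# Methods

## Model

The package models an isolated medfly population under sterile-male releases
with nine compartments: non-flying stages A (eggs through pupae, sharing a
carrying capacity K), wild males M, released sterile males M_S, once-mated
females F_W (fertilised) and F_S (sterilised), and double-mated females
F_WW, F_WS, F_SW, F_SS indexed by partner order.  Assumptions:

* Large, well-mixed population; all processes simultaneous and continuous in
  time (ODEs), except releases, which may be instantaneous pulses.
* At most two matings per female.  F_S and F_SS females have fully sterile
  progeny; residual fertility acts through a proportion ε of sterile males
  carrying fertile sperm, so a maturing female is fertilised with probability
  (M + εγM_S)/(M + γM_S).
* Male-only releases (a genetic sexing strain is assumed), sterile-male
  mortality μ_S independent of everything else — which is what makes the
  pulse train solvable in closed form and the reduced 7-state system exact.
* No migration, no seasonality, no spatial structure.

Density dependence enters only through the egg-laying term
(1 − A/K); {A ≤ K} is forward invariant and the model is homogeneous of
degree 1 in (K, Λ, state), so all release *ratios* are K-free.  K defaults to
10⁴, an arbitrary convention.

## Parameters (per day unless noted)

Peach-host presets, derived in `scenarios` from published cohort data:

| symbol | default | derivation |
|---|---|---|
| b_W | 12.135 | 13.19 eggs/day × 0.92 hatch |
| ν_A | 0.0365 | 0.6609 immature survival / 18.1 d development |
| μ_A | 0.0187 | (1 − 0.6609)/18.1 |
| r | 0.53 | female fraction at emergence |
| μ_F, μ_M | 1/42.66, 1/50.33 | reciprocal adult lifespans |
| μ_S | ln 2/3 ≈ 0.2310 | 3-day field half-life of sterile males |
| γ | 0.6129 / 2.03 | RSI/(1−RSI), without / with ginger root oil (GRO) |
| δ, δ_S | 0.16, 0.3161 (no GRO); 0.1, 0.2361 (GRO) | re-mating proportion ÷ refractory period |
| b_WW | (4.1765/3.22)·b_W | double- vs single-mated lifetime fecundity |
| b_WS, b_SW | case-dependent | cases 1–4: (0.5, 0.5), (0.4717, 0.6553), (0.1532, 0.65), (1, 1) × b_W |
| μ_F,WW | μ_F (default) or (27/34)·μ_F | see below |

Where a circulating printed constant and its own arithmetic differ in the
last digit (δ_S = 0.3161 vs 0.64/2.02 = 0.31683; γ = 0.6129 vs the RSI value
it implies), presets carry the printed constant so that the reference tables
are reproduced digit-for-digit; the `derive_*` functions keep the raw
arithmetic.  Likewise b_W, ν_A, μ_A are rounded to their circulating
precision by default (`rounding="exact"` disables this).  For μ_F,WW two
conventions exist in the source literature; the default μ_F,WW = μ_F is the
one consistent with the reference offspring-number table, and
`muFWW_mode="27over34"` exposes the longevity-based alternative; threshold
results are nearly insensitive to the choice because the F_WW path enters the
linearisation only through the small product δε.

## Thresholds

Linearising the reduced system at the origin under sterile-male saturation
(mating fractions degenerate to p_W = ε) gives the per-immature offspring sum
E(ε) (`thresholds.offspring_sum`); the origin is locally stable iff
E(ε) < 1.  E is quadratic in ε,

    E(ε) = N(δ)[(1 + a)ε + F̂ ε²],

with a collecting the sterilised re-mating paths and F̂ = F/b_W the
normalised trade-off, so ε_max is the smaller positive root of
N F̂ ε² + N(1+a)ε − 1 = 0, evaluated in the cancellation-safe form
2/(b + √(b² + 4NF̂)).  Degenerate inputs: if the root exceeds 1 (or the
discriminant is negative, possible only for strongly negative F̂), the
ceiling is capped at 1 with a warning — even fully fertile releases cannot
destabilise extinction of such a population.  Without re-mating the root
collapses to 1/R(0) exactly, which the tests assert to machine precision.

## Critical release rates

**Continuous.**  At steady state with M_S = Λ/μ_S every compartment can be
eliminated in favour of M, leaving one scalar residual g(M) on
(0, M_max = (1−r)ν_A K/μ_M).  Root counting uses a 2000-point scan
(log-spaced near 0, where the Allee-threshold root lives, plus a uniform
tail) with `brentq` polishing; every located root is validated in tests by
back-substitution into the ODE right-hand side (residual < 10⁻⁸ K).  The
critical rate is bisected on the 2-roots → 0-roots transition to a relative
tolerance of 10⁻³.  Stability of the two equilibria (lower repelling — the
strong Allee threshold — upper attracting) is checked by simulation, not
proved.

**Pulsed.**  Releases of τΛ_per males every τ days make M_S a closed-form
geometric pulse train; freezing it at its periodic extrema yields monotone
bounding systems which bracket the pulsed critical rate:

    (1−e^{−μ_S τ})/(τμ_S) Λ_cont ≤ Λ_per ≤ (e^{μ_S τ}−1)/(τμ_S) Λ_cont.

Within this bracket the rate is bisected on an elimination-vs-persistence
classifier, to an absolute tolerance of 0.25 on the ratio τΛ_per/M₀* (about
the resolution at which programmes are planned).  As τ → 0 the bracket
itself collapses onto Λ_cont, so the continuous limit needs no simulation.

**Classifier.**  Each probe simulates the impulsive system from the wild
equilibrium (sterile compartments empty, first pulse at t_S = 100 d) to a
horizon of 15 000 d.  *Elimination*: total wild-origin population below 10⁻⁶
of its pre-release value.  *Persistence*: the mean of the per-period samples
over the last 20 release periods exceeds 10⁻² of pre-release and two
consecutive window means differ by < 0.1 % (convergence to a positive
periodic orbit).  An undecided probe retries once with a doubled horizon,
then raises.  All thresholds are keyword-configurable.

## Integration

`scipy.integrate.solve_ivp` with LSODA (stiff-capable, adaptive), rtol 10⁻⁸ /
atol 10⁻⁸ for trajectory output and rtol 10⁻⁶ / atol 10⁻⁸ inside the
classifier; outputs are clipped at 0 (the flow is positivity-preserving, so
clipping only removes solver-level noise of order atol).  Pulses use
integrate–restart semantics: the flow stops at each release instant, M_S
jumps by τΛ_per, integration restarts — no smoothing.  Trajectories are
sampled on a 1-day grid by default; the classifier records segment endpoints
only.  Step-size convergence (halving `dt_max` changes the final state by
< 0.1 %) is asserted in the test suite.

## What the presets do and do not emulate

The presets are point estimates from heterogeneous laboratory and field
studies on one host fruit (peach).  They emulate the *structure* of the
decision problem — how thresholds move with re-mating asymmetry, double-mated
fecundity, competitiveness and residual fertility — not any particular
orchard.  Real populations add seasonality, spatial aggregation, host
succession and parameter uncertainty, none of which is modelled; passing
tests demonstrate internal correctness and reproduction of the reference
table anchors, not predictive accuracy in the field.

## Known limitations and deviations

* The GRO arm of the basic-offspring-number reference table cannot be
  reproduced: R(0) involves no GRO-dependent parameter, so the model yields
  the same R(0) for both arms.  `table_offspring` emits the computed GRO row
  with a discrepancy flag.
* The computed critical 3-day pulse ratio for case 2 without GRO at ε = 0 is
  ≈ 61.3, below previously reported estimates near 68.  The bisection itself
  certifies both sides at the 15 000-day horizon: probes just above 61.3
  reach the 10⁻⁶ elimination criterion, probes just below converge to a
  positive periodic orbit at a large fraction of the pre-release population.
  Near the threshold the time to elimination diverges, so any finite-horizon
  classification biases the estimate upward; estimates obtained with faster,
  shorter-horizon schemes are expected to land above ours, which is the
  likely origin of the gap.  The classifier keywords (`horizon`, `elim_frac`,
  ...) let users reproduce shorter-horizon estimates if they wish.
* Relatedly, the continuous-release ratio gain from GRO treatment computed
  here is ≈ 3.3 in every scenario — essentially γ_GRO/γ_noGRO, as expected
  from the exact invariance of the critical γΛ — not the "nearly 10"
  sometimes quoted; the pulsed-release gain (a factor ≈ 3–4) matches the
  quoted values.
* Stability and basin statements rest on numerical evidence (long-run
  simulation, bounding systems), not proofs.  No optimal-control release
  scheduling, no seasonality, no spatial effects.
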