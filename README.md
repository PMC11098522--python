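# medfly-sit

Population-dynamics toolbox for planning Sterile Insect Technique (SIT)
programmes against the Mediterranean fruit fly (*Ceratitis capitata*) when two
real-world imperfections matter: **residual fertility** of the released males
(a fraction ε of their sperm is still fertile) and **female re-mating**
(females may mate again, possibly switching between wild and sterile
partners).

It is written for quantitative ecologists and SIT programme designers who
need to answer two questions before committing to a release campaign:

1. *How sterile is sterile enough?*  Above a ceiling ε_max the extinct state
   is never stable, no matter how many males are released.
2. *How many males per wild male must be released*, continuously or as pulses
   every τ days, to drive the population extinct?

## The model

A compartmental ODE system tracks non-flying stages A (larvae + pupae, logistic
competition with carrying capacity K), wild males M, sterile males M_S, and
six mated-female classes: F_W, F_S (once mated, by a wild / sterile male) and
F_WW, F_WS, F_SW, F_SS (double mated, by partner order).  A newly mature
female is fertilised with probability

    p_W = (M + ε γ M_S) / (M + γ M_S),        p_S = 1 − p_W,

where γ is sterile-male mating competitiveness (γ = RSI/(1−RSI)).  Re-mating
moves F_W females onward at rate δ and F_S females at rate δ_S ≥ δ.  Each
fertile female class lays hatched eggs at its own rate b_W, b_WW, b_WS, b_SW.

Closed forms implemented in `medfly_sit.thresholds`:

* basic offspring numbers
  N(δ) = b_W r ν_A / ((ν_A+μ_A)(μ_F+δ)) and
  R(δ) = N(δ)(1 + (b_WW/b_W)(δ/μ_F,WW));
* the re-mating trade-off
  F(δ, δ_S) = δ(b_WW/μ_F,WW − b_WS/μ_F,WS) − δ_S (b_SW/μ_F,SW)(δ+μ_F)/(δ_S+μ_F),
  whose sign decides whether re-mating helps or hurts SIT;
* the residual-fertility ceiling ε_max, the root in (0, 1] of the
  origin-linearisation condition E(ε) = 1 (equal to 1/R(0) without
  re-mating);
* the wild equilibrium (A*, M*, F_W*, F_WW*), existing iff R(δ) > 1.

`medfly_sit.dynamics` and `medfly_sit.impulsive` integrate the continuous and
pulsed-release systems (pulses of τΛ_per males every τ days, closed-form
sterile-male pulse train, monotone bounding systems).
`medfly_sit.critical` finds critical release rates: a scalar equilibrium
equation plus root counting for continuous releases (the fold pattern
1 → 2 → 0 equilibria as Λ grows), and bisection on
elimination-vs-persistence of simulations for pulsed releases.
`medfly_sit.scenarios` carries the peach-host medfly presets (4 fecundity
cases × 4 re-mating modes × ginger-root-oil treatment on/off) and regenerates
the reference tables and sweep curves.

## Worked example

Thresholds for fecundity case 2 (b_WS = 0.4717 b_W, b_SW = 0.6553 b_W),
differential re-mating (δ = 0.16, δ_S = 0.3161 per day), no GRO treatment,
residual fertility 0.2 %:

```sh
$ medfly-sit thresholds --case 2 --remating differential --eps 0.002
{
  "N0": 181.42214111413043,
  "N_delta": 23.18316053901687,
  "R0": 181.42214111413043,
  "R_delta": 228.42698115142733,
  "F_tradeoff": 10.429119956421374,
  "eps_max": 0.004793902632488207
}
```

A once-mated female leaves ~181 female offspring over her lifetime (R0);
re-mating raises this to ~228 (R_delta).  The positive trade-off term says
re-mating is net-beneficial for the *wild* population here, and sterilisation
can only work if residual fertility stays below ε_max ≈ 0.48 %.  The chosen
ε = 0.2 % is admissible, so a finite critical release rate exists:

```sh
$ medfly-sit critical --case 2 --mode continuous
{
  "mode": "continuous",
  "value": 168141.714767418,
  "ratio": 19.559747001425947,
  "M0star": 8596.313375380576,
  ...
}
```

At ε = 0 one must release about 19.6 sterile males per wild male per day
(times μ_S for the standing-population equivalent) to destroy every positive
equilibrium; `--mode periodic --tau 3` instead bisects pulsed-release
simulations.  Ratios are independent of K by the model's scale invariance.

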