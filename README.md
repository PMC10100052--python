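# settlemate

Why do territorial songbirds settle near each other? Because conspecifics
make good habitat easier to *find*, because their choices are *copied*, or
because clustered males attract more *females*? `settlemate` implements the
two statistical analyses that separate these hypotheses for
settlement-and-pairing data, together with a seeded synthetic-data
generator so the whole pipeline is testable without field data.

1. **Settlement analysis.** Settled-male locations per site-year are
   modelled as an inhomogeneous Poisson point process with loglinear
   intensity λ(u) = exp(β₀ + Σ βₖ Sₖ(u)), fitted jointly across site-years
   by Berman–Turner quadrature (a weighted Poisson regression built from
   first principles). Covariates: a leave-one-site-year-out kernel-density
   surface of cumulative nest locations (*hab*, habitat attractiveness)
   and distance-decay proximity to song-playback stations
   (*prox* = e^(−d/200 m)). Candidate models are compared by AICc and
   coefficients by range standardisation exp(β × range).
2. **Mate-choice analysis.** Each female chooses among the males present
   when she began nesting; male i's attractiveness is the power function
   A_i = H_i^α₁ · C_i^α₂ of habitat value H and connectivity
   C_i = Σ_{j≠i} e^(−d_ij/decay) (playbacks may count as competitors but
   are never choosable), with conditional-logit choice probability
   p_i = A_i / Σ_j A_j. The four models (null / habitat / connectivity /
   both) are fitted by maximum likelihood and compared by AICc; exponents
   translate to percent changes via 100 × (1.1^α − 1) per 10% step.

Intended for behavioural ecologists analysing settlement point patterns
and sequential mate choices on planar metre coordinates, and as a worked
reference implementation of both estimators.

## Worked example

Generate a five-site synthetic study at the default effect sizes
(β_hab = 0.109, β_prox = 1.773; α₁ = 0.625, α₂ = −0.06; 59 choices), then
run both analyses:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_settlement_ppm.py
python analysis/03_mate_choice.py
```

The settlement comparison prints:

```
Model                 AICc   dAICc  w_i
hab+prox.all       1512.54    0.00  0.96
hab                1519.03    6.49  0.04
prox.all           1542.76   30.22  <0.01
null               1549.57   37.03  <0.01

range-standardised density factors (best joint model):
  hab       beta=0.131  exp(beta x range)=72.709
  prox.all  beta=2.064  exp(beta x range)=6.641
```

— the joint habitat + proximity model wins, and across its observed range
habitat moves predicted male density by a much larger factor than playback
proximity: males track habitat first, conspecific song second. The
mate-choice comparison prints:

```
Model                    AICc   dAICc  w_i   alpha1   alpha2
hab                    233.31    0.00   0.74    0.528    0.000
hab+connectivity       235.37    2.06   0.26    0.538   -0.134
connectivity           278.23   44.92  <0.01    0.000    1.211
null                   282.16   48.85  <0.01    0.000    0.000

per 10% covariate increase (best model):
  habitat:      +5.2% in choice odds
  connectivity: +0.0% in choice odds
```

— habitat carries essentially all the support, the habitat exponent is
strongly positive (a 10% better territory raises a male's odds of being
chosen by ~5%), and connectivity adds nothing (its exponent is slightly
negative in the joint model): clustered males gain no pairing benefit.
`analysis/04_recovery_checks.py` re-estimates the generating parameters
from fresh simulations and prints recovery errors and Wald coverage.

The same steps are available as a CLI on files
(`settlemate simulate|preprocess|covariates|fit-ppm|fit-choice|compare|run`),
e.g. `settlemate run --config config.yml --out runs/demo` executes the
whole pipeline into a run directory with both comparison tables and a
JSON summary.

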