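# Methods

## Setting and assumptions

Data are i.i.d. two-stage SMART trajectories `(Z1, A1, Z2, A2, Y)`:
baseline covariates `Z1`, stage-1 treatment `A1`, post-stage-1
covariates `Z2` (which may include an embedded tailoring variable
deciding who is re-randomized), stage-2 treatment `A2` (defined only for
re-randomized subjects), and a final outcome `Y` with smaller values
preferred. Histories are `H1 = Z1` and `H2 = (Z1, A1, Z2)`. The causal
assumptions are the standard ones for sequential randomization —
consistency, sequential ignorability (guaranteed by randomization), and
positivity — plus a fixed allocation ratio with treatments coded so that
`E(Ak) = 0`. The coding constraint is enforced at construction time
(`TreatmentCoding` rejects codes whose expectation under the declared
allocation is nonzero, e.g. ±1 requires 1:1, while 2:1 must be coded
+1/−2): the omitted-variable-bias behaviour of the stage-2 fit depends
on it. Only binary arms per stage are supported; the coding abstraction
is the extension point for multi-arm designs, where the expected-regret
functional no longer reduces to an absolute value.

## Q-functions and the four learners

Both stages use linear Q-functions with separate main-effect and
treatment-effect blocks,

```
Qj(Hj, Aj) = X̃j0' βj0 + Aj X̃j1' βj1,    X̃j0 = (1, Xj0')', X̃j1 = (1, Xj1')',
```

fit by OLS, stage 2 first and restricted to re-randomized subjects. Main
and effect term lists are declared independently (`ModelSpec`); software
that forces a shared design hides exactly the omission issue these
methods address. The fitted stage-2 contrast is `t̂ = X̃21'β̂21` and the
stage-2 rule is `d̂2 = −sgn(t̂)` with `sgn(0) = 1`, so an exact tie maps
deterministically to arm −1 (a probability-zero event under the usual
regularity condition that `P(X̃21'ψ21 = 0) = 0`, but the code must be
deterministic). The same tie convention applies at stage 1 and to
general codings (choose the arm minimizing `a·t̂`; ties to the smaller
code).

Stage 1 then estimates `E(Yopt | H1, A1)` where
`Yopt = E(Y | H2, A2 = d2opt)`. The learners:

- **Q (standard)** — pseudo-outcome `Ŷopt = X̃20'β̂20 − |t̂|`, regressed
  on `[X̃10 | A1 X̃11]` over all subjects. Discards the stage-2 residual:
  whatever the stage-2 main-effect model failed to capture is lost.
- **mQ (modified)** — pseudo-outcome `Ŷopt = Y − A2 t̂ − |t̂|`, i.e. the
  observed outcome plus the estimated regret
  `min_a2(a2 t̂) − A2 t̂ ≤ 0`, zero exactly when the subject received the
  estimated-optimal stage-2 arm. Retaining `Y` keeps the stage-2
  residual in the stage-1 response, which matters when the stage-2
  main-effect model omits a real term (e.g. a `Z1·A1` interaction): the
  omitted signal is still in the residual and is picked up by the
  stage-1 regression. The source method is specified via a regret
  function without an explicit pseudo-outcome formula; the form above is
  this package's reconstruction from the counterfactual identity
  `Yopt = E(Y | H2, A2 = a2) + (d2opt − a2)·X̃21'ψ21`, of which it is the
  plug-in estimate.
- **IQ (interactive)** — models the two ingredients separately:
  `m̂(H1, A1)` from regressing the fitted stage-2 main effect
  `X̃20'β̂20` on `[X̃10 | A1 X̃11]`, and a conditional law
  `ĝ(t | H1, A1)` for the contrast; then
  `Q̂1(h1, a1) = m̂(h1, a1) − E_ĝ[|t|]`. Taking the expectation of `|t|`
  under a fitted conditional law avoids the misspecification a plain
  linear regression of a pseudo-outcome containing `|t̂|` commits, since
  `|t|` is nonlinear in stage-1 predictors.
- **mIQ (modified interactive)** — IQ with the `m`-regression response
  replaced by `Y − A2 t̂` for re-randomized subjects. This is the only
  difference from IQ, and it is what restores robustness to stage-2
  main-effect omissions; the `g` step is shared. (The source text
  nominally locates the modification in the `g` step, but the change it
  describes — incorporating the stage-2 residual — is the `m`-response
  change; that reading is implemented here.)

Subjects not re-randomized (embedded tailoring) had no stage-2 choice;
their single continuation is by design their optimal one, so they enter
every stage-1 regression with their observed `Y` as response. Their
contrast `t̂` is still defined (a function of `H2`), and a config switch
(`g_rows = rerandomized | all`, default `rerandomized`) controls whether
their rows enter the `g` regression; the default excludes them because
`|t̂|` corrects a stage-2 randomization they never faced.

## The g-model

`g` is fit by regressing `t̂` on the same stage-1 design
`[X̃10 | A1 X̃11]` used for `m̂` — the minimal reading of "regress the
contrast on (H1, A1)", and it keeps the location `μ̂` evaluable at both
arms. Two kinds:

- **normal** (default): `t | H1, A1 ~ N(μ̂(H1,A1), σ̂²)` with constant
  variance; `E|t|` is the folded-normal mean
  `σ√(2/π)·exp(−μ²/(2σ²)) + μ·(1 − 2Φ(−μ/σ))`, degenerating to `|μ|` at
  `σ = 0`.
- **empirical**: a homoscedastic location-shift model; `E|t|` is the
  average of `|μ̂ + êj|` over the pool of centered OLS residuals. This
  relaxes normality; covariate-dependent scale or kernel conditional
  densities are out of scope.

All residual standard deviations use denominator `n − p` (defined as 0
when `n = p`); the source does not specify MLE vs unbiased and the
difference is `O(p/n)`.

## Numerical choices

OLS is solved by `numpy.linalg.lstsq` after an explicit rank check;
rank-deficient designs raise an error naming the collinear columns
(located by QR with column pivoting) instead of silently falling back to
a pseudo-inverse — collinearity here almost always means a mis-declared
model, and masking it would reintroduce the overfitting failure mode
these methods are meant to expose. Design matrices are built
deterministically: intercept first, then terms in declared order, main
block before treatment block, so coefficient vectors are reproducibly
indexed. Loading from CSV is complete-case with a logged dropped-row
count; the re-randomization flag is authoritative and never inferred.

## Simulation harness

The generator draws `Z1 ~ N(−2, 1)`, `Z2 = Z1 + N(0, 4)`, balanced ±1
treatments at both stages (no embedded tailoring), and

```
Y = 3 − Z1 + 0.1·A1 − 0.1·Z2 + c1·Z1·A1 + c2·A2·(−6 − 4Z1 + 5A1 − 0.2Z2) + N(0, 1),
```

where `c1` scales stage-1 effect heterogeneity (the `Z1·A1` term that
the analysis model deliberately omits from the stage-2 main block) and
`c2` scales stage-2 effect heterogeneity. The analysis models are
intentionally plain: stage-2 main and effect blocks `(1, Z1, A1, Z2)`,
stage-1 blocks `(1, Z1)`. These defaults (with n = 250 per replicate,
N = 10,000 evaluation subjects, 1000 replicates) are the study
conditions the harness emulates.

Evaluation uses one population per `(c1, c2)` scenario, shared across
replicates and methods (its seed derives deterministically from the
master seed and the scenario coordinates). Truth is tabulated from the
noise-free expected potential outcomes `μi(a1, a2)` over the four
regimes, conditional on each subject's realized `(z1, z2)`; since a
stage-1 decision cannot observe `z2`, this caps attainable PCI below 1,
matching the convention of the results being replicated. Metrics:

- **PCI** — fraction of the population with `d̂1 = d1_true`;
- **value bias** — population mean of `Q̂1(z1, d̂1) − v_opt`, `v_opt` the
  true four-regime minimum.

The per-population bias mean itself varies across population draws
(between-population SD up to ~0.06 at strong heterogeneity), which is
why replication tests average several independent draws.

What the generator does *not* emulate: embedded tailoring (every
simulated subject is re-randomized — the loader and learners support
non-re-randomized subjects, exercised in unit tests with constructed
data), non-normal or heteroscedastic contrast distributions, missing
data, and `Z2` laws that depend on `A1`. Passing the simulation suite
therefore demonstrates correctness of the estimators under the stated
generative law, not robustness to those real-data features.

The omitted-variable-bias oracle computes
`bias = E[X'X]⁻¹ E[X'V] γ` for the included stage-2 design `X` and
omitted columns `V` (default `Z1·A1` with weight `c1`), with moments
averaged over `mc_n` Monte-Carlo draws (default 10⁶) of the generative
law. A zero `γ` yields an exactly zero vector. It reproduces hand
results (omitting `A2·Z1·A1` biases only the `A2·A1` coefficient, by
`γ·E[Z1] = −2γ`) and matches brute-force refitting coefficient by
coefficient.

Randomness is managed by named `SeedSequence` substreams
`(seed, c1-key, c2-key, tag, rep)`, so replicates are order-independent
and method order never affects results.

## Known limitations

- Point estimation only: no confidence intervals for stage-1 quantities
  (nonregular asymptotics under weak stage-2 effects are untreated).
- Two stages, two arms per stage; no inverse-probability weighting for
  observational confounding; no repeated-measures outcomes.
- The empirical `g` shifts a single residual pool: conditional variance
  is assumed constant in `(H1, A1)`.
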