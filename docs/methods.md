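# Methods

## Model

The cooperation-and-punishment model is a two-tree multinomial
processing tree (MPT). Per experimental condition (stratum), trials
against defecting partners and trials against cooperating partners form
two independent multinomials with four categories each: own choice
(cooperate/defect) × punishment (yes/no). The cooperation probability
`C` is structurally shared between the two trees of a stratum. The
outcome-contingent punishment processes are `P_Moral` (cooperated,
partner defected), `P_Hypocritical` (defected, partner defected) and
`P_Antisocial` (defected, partner cooperated); after mutual cooperation
no outcome-contingent process exists. Whenever the contingent process
does not fire, the unspecific bias `b` may still produce punishment, so
a cell with process `P` punishes with total probability `P + (1−P)·b`
and the mutual-cooperation cell with probability `b`. All parameters
live on the probability scale; category probabilities within a tree sum
to one by construction.

Each stratum contributes 6 independent data cells (2 trees × 3), so a
model with `k` free parameters over `S` strata is tested on
`6S − k` df. The two-condition base model (10 free parameters) has 2 df.

## Estimation

Fitting maximizes the product-multinomial log-likelihood
`Σ n·log p(θ)`. Parameters are optimized on the logit scale with
L-BFGS-B and the analytic gradient (the chain rule through the
polynomial category probabilities); estimates are clamped to
`[1e-6, 1−1e-6]`, which keeps G² finite at degenerate cells while
moving probabilities by less than 1e-5. Boundary values remain legal
inputs to the probability map itself.

Because the likelihood can be multimodal under heavy parameter tying,
each fit uses multiple restarts: the first start is the centre of the
parameter cube, the rest come from a seeded scrambled Sobol draw;
the best likelihood wins, with exact ties broken to the
lexicographically smallest parameter vector so that results are
reproducible. The library default is 20 restarts; the Monte-Carlo
calibration loops in the test suite use 1–3 because their null-data
likelihoods are effectively unimodal, which the grid-search oracle
cross-checks. Strata that share no free identifier are fitted as
independent blocks (the likelihood separates exactly); this keeps the
40-stratum round-level model fast without changing the optimum.

Goodness of fit is `G² = 2·Σ n·ln(n/m)`, computed as twice the
log-likelihood gap to the saturated model; zero observed cells
contribute nothing (standard convention), and a zero expected cell
facing a positive observation reports `inf` rather than an arbitrary
large number. Nested models are compared with `ΔG² = G²_r − G²_b`,
chi-square with df equal to the number of independent restrictions;
nesting of the tying maps is verified structurally before any fitting.
Negative ΔG² beyond a 1e-6 numerical allowance raises an error instead
of being silently clipped, since it indicates a failed base fit.

Standard errors are Wald: square roots of the diagonal of the inverse
observed information, where the information is the negative Hessian of
the log-likelihood at the MLE on the probability scale, obtained by
central differences (step 1e-5) of the analytic gradient. Estimates at
the boundary, or parameters in a singular information block, are
reported as NaN. Whether the original analyses used observed or
expected information is not documented; the two agree at interior MLEs
to the accuracy relevant here, and the Monte-Carlo calibration test
(estimate SD vs mean reported SE over 200 replications, within 15%)
covers the choice.

Effect sizes use `w = sqrt(ΔG²/N_total)` where `N_total` is the total
number of Prisoner's Dilemma trials across both conditions
(participants × 20). This is the only convention consistent with every
published (ΔG², w) pair, and it is asserted against all thirteen
numerically printed pairs in the tests.

## Power and sensitivity

The minimal detectable effect of a design solves
`P(X > χ²_{1−α,df}) = 1−β` for the noncentrality λ of a noncentral
chi-square variable `X`, by Brent root-finding on `[1e-8, 1e6]`
(relative tolerance 1e-12); then `w = sqrt(λ/N_total)`. The inverse
view (`power_at`) evaluates the noncentral upper tail at
`λ = w²·N_total` and round-trips with the solver to 1e-6. Display
rounding follows the field's reporting style: two decimals for w, three
for p. Published p-values are matched to ±0.002 because the printed
statistics are themselves rounded to two decimals (e.g. a statistic
printing as 0.18 on 2 df has p anywhere in ≈0.912–0.915).

## Synthetic experiments

The simulator emulates the experimental paradigm: 20 one-shot rounds
per participant against 20 programmed partners, half cooperating and
half defecting, in a uniformly random seeded order per participant;
rounds 1–4 flagged as practice (included in analyses by default, as in
the published analyses); payoffs +10/+10, 0/0, −10/+20, +20/−10;
punishment as an investment of 1..max_invest units deducting ten times
the investment from the partner; programmed partners morally punish
unilateral defection with a uniform magnitude from {10,…,50} cents;
account balances tracked from the starting endowment with a
floor-at-zero rule (the second experiment's configuration —
endowment 80, max invest 3 — cannot go negative by construction).

Choices are drawn generatively from the model: cooperate with
probability `C`, then punish with the trial's cell-conditional
punishment probability. The model treats punishment as binary, so
invested amounts are drawn uniformly on the allowed range; this is a
stand-in — the empirical magnitude distribution is not modelled — and
analyses only ever dichotomize `punish_invested > 0`. An optional
per-round linear drift on one parameter exercises the across-rounds
stability analysis under violation. Identical seeds give byte-identical
tables.

What passing tests on these data do show: the estimator recovers
generating parameters at the studies' scale (each parameter within 3 SE
of truth in ≥95% of 200 replications), the 1-df equality test holds its
nominal type-I error (0.05 ± 0.02 over 1000 null datasets), and the
pipeline carries the published test structure (2-df base fit, 1-df
battery, 38-df stability). What they do not show: agreement with the
published estimates themselves, which depend on the deposited
participant data; real data also contain participant heterogeneity and
sequential dependence that the i.i.d. generative model omits, so
real-data G² values may exceed synthetic ones.

The preset designs in `coop_punish.studies` fix the sample sizes,
condition structure, endowments and punishment ranges of the three
experiments; their generating parameter values were chosen once as
field-realistic (cooperation near one half, moral punishment the
dominant process, bias below 0.1) with condition differences in the
reported directions, and are labelled illustrative in the code.

## Stability analysis structure

The across-rounds test stratifies by condition × round position
(2 × 20 = 40 strata). In the default structure all five parameters are
free per stratum in both compared models and only the moral-punishment
parameter is equated across the 20 rounds within each condition in the
restricted model — 19 restrictions per condition, 38 df, the only
structure consistent with the published df accounting. An alternative
reading (the other four parameters pre-tied across rounds in both
models) is available via `AnalysisConfig(stability_free_all=False)`.

## Known limitations

- Punishment magnitude is uniform in simulation and ignored in
  analysis; no magnitude model is provided.
- No hierarchical/latent-trait extension: parameters are per-stratum
  aggregates, so individual differences appear only through multinomial
  noise.
- Multiple testing across the five-parameter battery is uncorrected,
  matching the per-test α = 0.05 reporting convention.
- Wald intervals can be poor near parameter boundaries; the package
  reports NaN there rather than a fabricated value, and offers no
  profile or bootstrap intervals.
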