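# Methods

## Model and assumptions

The analysis treats race class `X`, BMI class `M1` and GWG class `M2` as
parents of a single eight-level interaction node whose levels enumerate
every (X, M1, M2) combination; the parameter attached to level *i* is the
potential outcome `PO[x, m1, m2]`, the probability of the adverse outcome
under that joint assignment. Identification of the controlled direct
effects rests on the usual no-unmeasured-confounding assumptions for both
the exposure–outcome and mediator–outcome relations; with everything
binary and the interaction saturated, no functional-form assumptions are
added.

Cases per cell are `r_i ~ Binomial(n_i, PO_i)` with independent
`Uniform(0,1)` priors, so the model factorizes and each posterior is
exactly `Beta(1 + r_i, 1 + n_i − r_i)`. With zero observations a cell's
posterior degrades to the Uniform prior (a logged warning, not an error).

Marginal potential outcomes with an NA index (e.g. `PO[2,1,NA]`) are fit
on the *pooled* counts of the collapsed cells — the same thing as handing
the aggregated data row to the binomial likelihood. The alternative
reading (a prevalence-weighted mixture of cell posteriors) has the same
large-n limit, the law-of-total-probability mean; the pooled-count form
was chosen because it is what an aggregated data row does, and a test pins
the large-n agreement.

## Estimation

The default engine draws S independent samples per potential outcome
directly from the exact Beta posterior. Defaults mirror the iterative
protocol the model family is usually run under: S = 10,000 kept draws,
burn-in 5,000 (relevant only to the chain mode), 2 chains, equal-tailed
95% credible intervals from the 2.5/97.5 posterior percentiles, and the
zero-exclusion significance rule.

`gibbs_mode` provides a genuine iterative sampler for validation:
random-walk Metropolis on logit(p) per cell, proposal scale adapted
toward ~44% acceptance during burn-in only, chains started at disparate
values (p = 0.05 / 0.95), split potential-scale-reduction reported, and a
non-convergence warning above 1.05. Because the full conditionals here
are conjugate, a textbook Gibbs sweep would be an independent Beta draw —
identical to the default engine and useless as a cross-check; the
Metropolis kernel is a deliberately different route whose agreement with
the closed form (quantiles within Monte-Carlo error, ESS-adjusted
two-sample distance) is asserted in the tests.

Seed policy: one master seed; every potential-outcome quantity derives a
substream seed from (master, outcome label, PO label) via a CRC hash
(all sub-seeds < 2³¹). A PO reused by several contrasts therefore
contributes the *same* draws — TE and CDE are paired per draw, which is
what makes the draw-wise PA ratio coherent. PA is computed per draw and
then summarized; medians do not commute with ratios, and a regression
test keeps the distinction honest. Draws with TE exactly 0 are excluded
from PA summaries with a logged count rather than clamped.

A consequence of labeling substreams by position (x = 1 vs 2) is that
swapping the race labels negates TE draws exactly only when the two
per-race substreams are exchanged along with the labels; under a plain
label swap the negation holds in distribution. Keying substreams by the
counts instead would make two races with identical data produce a
zero-width TE posterior, which is wrong, so the positional labeling
stays.

## Mediator derivation and deletion rules

BMI = weight/height² (kg/m²) from prepregnancy weight; GWG = delivery
weight − prepregnancy weight, corrected to 40 weeks by proportional
scaling `× 40/weeks` — the simplest linear correction with value 0 at
zero gain (the exact correction used on the source data is not public).
Optimal BMI is [18.5, 25.0), half-open at 25 because the guideline's
upper normal value is 24.9; optimal GWG is the closed [11.5, 16.0] kg.
Both conventions are configurable (`ClassificationRules`). Negative
adjusted GWG is retained and classified non-optimal; no plausibility
trimming is applied — the only deletions are (1) any missing outcome,
then (2) any missing or non-positive anthropometric field, logged in that
order. Readers accept metric or imperial units (2.54 cm/in,
0.45359237 kg/lb) and a configurable numeric sentinel list mapped to
missing.

## Synthetic data

The generator's defaults are the study conditions: joint mediator
prevalence per race from the published table (the printed Black column
sums to 99.9% and is renormalized to 100%), cohort sizes 14M non-Black /
3M Black, and cell probabilities calibrated so the generating TE and CDEs
equal the published values. Baseline (non-Black) rates used for
calibration: gestational hypertension 0.05, hypertension-eclampsia 0.01,
induction 0.30, cesarean 0.25, ICU admission 0.002 — plausible US rates.

Calibration solves a linear system: x=1 cells all at the baseline; each
CDE target pins (or, given cells already pinned, solves via the
conditional-prevalence weights) the x=2 cells at the constrained optimal
levels; all remaining x=2 cells share one rate solved from the TE target.
Any solved probability outside [0,1] raises an error naming the violating
cell, and every returned solution is forward-verified by recomputing the
contrasts (tolerance 1e-12).

Record-level generation back-solves anthropometrics from the drawn
classes: BMI uniform within the class interval (optimal [18.5, 25);
non-optimal a length-weighted mixture of [15, 18.5) and [25, 45]),
adjusted GWG likewise (optimal [11.5, 16]; non-optimal [0, 11.5) ∪
(16, 30]), gestation uniform on [37, 42] weeks, height uniform on
[150, 180] cm, and weights reconstructed so derivation reproduces the
drawn classes. Missingness is missing-completely-at-random per field.
What this emulates — and what it does not: real anthropometrics are not
uniform within class, mediators are correlated with age/parity, and real
missingness is unlikely to be MCAR; passing tests therefore demonstrate
correctness of derivation, deletion accounting, aggregation and
inference, not robustness to informative missingness.

## Problem sizes and numerical choices

Cell-level recovery simulations run at the full 14M/3M cohort scale (the
model consumes only eight binomial counts, so this is essentially free);
the record-level prevalence round trip uses 1M births per race, and
coverage checks use 200 replicate cohorts of 100k per race with S = 2000.
At the full scale the recovered percent-attributable values carry a
cohort-sampling standard error of roughly 2–5 percentage points (≈14 for
the rare ICU outcome), which is the natural scale for recovery
tolerances; delta-method SE helpers in `replication` make those bounds
explicit. Percentiles use NumPy's linear interpolation; summaries require
S ≥ 100. Ties at interval endpoints count as containing zero
(non-significant).

## Known limitations

* Controlled direct effects only; natural direct/indirect decompositions
  are out of scope.
* Single race contrast (Black vs all others); no multi-race extension.
* No covariate adjustment or hierarchical structure; the eight-cell model
  is saturated by design.
* The percent attributable is unstable when TE ≈ 0; such rows are flagged
  (`stable = False`) rather than suppressed.
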