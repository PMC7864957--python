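# Methods

## Phenotype classification

The unit of scoring is the hemisegment: one lateral half of a repeating
embryonic segment, carrying in the wild type four Tin-CCs, two Svp-CCs and
two Svp-PCs. The classifier applies four deterministic rules, in order:

1. **specification** — `tin_cc == 0 and svp_cc == 0`: no cardial cells
   formed, so no division can be scored. If set, the division flags are
   all false and the hemisegment is excluded from division-defect
   denominators (it is tallied separately).
2. **symmetric** — `tin_cc != 4`.
3. **asymmetric** — `svp_cc != svp_pc`, or the enlarged-Svp-CC-nucleus
   flag. The flag covers karyokinesis failures that leave cell counts
   intact; it is scored at the microscope and accepted as boolean input —
   image analysis is out of scope for this package.
4. **earlier** — `svp_cc == svp_pc != 2`: one or three *complete* Svp
   pairs. The pair-matching test is deliberately strict: a mixed
   configuration such as (svp_cc, svp_pc) = (2, 1) is asymmetric only,
   never "earlier", because the earlier-division signature is defined on
   complete pairs. Division flags 2–4 may co-occur in one hemisegment.

Counts are validated as non-negative integers but not capped; values above
6 are logged as suspicious rather than rejected, since real mutants can
exceed the illustrated range.

Per embryo, the response used downstream is the proportion of scored
hemisegments carrying each defect category: `proportion = defect_count /
scored`, with `scored = total − specification`. Embryos enter the
regression models unweighted regardless of how many hemisegments they
contribute, because the response is defined per embryo. Per-genotype
summaries pool hemisegments (`Σ defective / Σ scored`), which is what a
percent-defective bar chart reports.

## Permutation inference

Regression assumptions (normality, homoscedasticity) are untenable for
small-sample proportion phenotypes, so all p-values are obtained by
permutation. Both engines report the Monte-Carlo estimator
p = (n+1)/(N+1), which is a valid p-value for any N; the default
N = 10⁶ makes p-values reproducible to ~10⁻³ relative error. Tests are
one-sided (upper tail): permuted coefficients *at least as large* as the
observed one count as exceedances. Counting ties as exceedances keeps the
p-value valid (never anti-conservative) for granular proportion data; a
strict-inequality option exists. Tie detection uses a relative tolerance of
10⁻¹² so that coefficients reached via different linear-algebra paths
(vectorised engine, enumeration oracle, explicit re-fit) agree on ties.

**Two-group test.** The OLS slope of Y on an intercept and the genotype
indicator equals the difference of group means; each permutation uniformly
re-assigns the labels (group sizes preserved). With only an intercept as
nuisance this scheme is exact under exchangeability.

**Synergy test.** The three-genotype design (single het A, single het B,
double het) saturates the no-intercept model Y = β1 I_n + β2 I_M +
β3 I_n I_M + ε, so β3 = ȳ_double − ȳ_A − ȳ_B. The no-intercept form is
forced: with three groups, the interaction column is an exact linear
combination of an intercept and the two main effects, so an intercept model
is unidentifiable. H0: β3 = 0 is tested with the Smith orthogonalization
procedure: z* (the interaction column residualised against I_n and I_M) has
its rows permuted; each re-fit of Y on (I_n, I_M, permuted z*) records the
coefficient on the permuted column. The vectorised engine computes that
coefficient via Frisch–Waugh — re-residualise the permuted z* against the
nuisance, then β = ⟨z̃, y⟩/⟨z̃, z̃⟩ — in blocks of 10⁵ permutations to bound
memory; permutations whose shuffled column falls exactly in the nuisance
span (undefined coefficient) are scored as ties, which can only make the
p-value larger. Observed β3 satisfies the same identity with z̃ = z*, which
the test suite checks to 10⁻¹⁰.

An optional four-group variant (`include_baseline=True`) adds an intercept
and lets wild-type embryos join the fit; it departs from the published
three-genotype contrast and is identifiable only because the fourth group
breaks the collinearity above.

**Exact oracles.** For small samples the full permutation distribution is
enumerable: all C(n, n₁) label assignments for the two-group test, all n!
row orderings of z* for the synergy test (limited to n ≤ 8, 40 320
orderings). These enumerations share no code path with the Monte-Carlo
engines and anchor their correctness in the test suite: Monte-Carlo
p-values must sit within 3·sqrt(p(1−p)/N) of the exact values.

**Randomness contract.** A single integer seed feeds
`numpy.random.default_rng`; permutations are independent uniform shuffles.
Identical inputs and seed give bit-identical results; different seeds agree
to Monte-Carlo error.

## Synthetic data generator

The generator emulates the embryo-level structure the inference assumes,
not the imaging process: each embryo contributes a fixed number of scored
hemisegments; each hemisegment draws one outcome from {none, asymmetric,
symmetric, earlier} with per-genotype probabilities; outcomes are rendered
as counts the classifier inverts exactly (symmetric → 3 or 5 Tin-CCs;
asymmetric → 3/1 or 1/3 Svp imbalance; earlier → 1 or 3 complete pairs).
One category per hemisegment keeps the generator↔classifier round trip
exact; co-occurring defects, which the classifier accepts, are simply not
generated. Specification defects are not simulated by default (they are
essentially absent in division-defect genotypes).

Defaults were fixed once from the design of a typical scoring experiment in
this system — roughly 180–240 hemisegments per genotype, here 16 embryos ×
12 hemisegments = 192; near-zero wild-type defect rates (0.005 per
category) and single-heterozygote rates of a few percent (0.04 per
category); default synergy increment δ = 0.10 on the probability scale. The
interaction is parameterised additively on probabilities (double = p_A +
p_B − p_0 + δ, clamped to [0, 1] with censoring logged) because the synergy
model tests additivity of group means of proportions.

Between-embryo overdispersion, when enabled, draws each embryo's outcome
probabilities from a Dirichlet with mean equal to the configured vector and
the given concentration; this is mean-preserving, respects the sum-to-one
constraint without clamping, and inflates between-embryo variance above the
binomial expectation (verified by test).

What passing tests on this generator do **not** show: robustness to
scoring ambiguity in real z-stacks, to co-occurring defects within one
hemisegment, to unequal hemisegment counts per embryo (supported in the
classifier but not generated), or to genotype-dependent embryo numbers.

## Comparative-Ct quantification

ΔCt = mean(target Ct) − mean(reference Ct) within a condition; ΔΔCt =
ΔCt_treated − ΔCt_control; fold = 2^−ΔΔCt with amplification efficiency
fixed at 2. Replicate scatter propagates by root-sum-square of the target
and reference sample standard deviations (the treated condition's ΔCt SD
defines the reported fold interval; the control's SD can be folded in by
callers that prefer a wider band). A single replicate yields SD 0 rather
than an error, so single-well pilots still quantify.

## Numerical choices and degenerate inputs

OLS uses `numpy.linalg.lstsq` after a QR-based rank check that names the
collinear columns. Degenerate cases: constant response → every permuted
coefficient ties the observed one → p = 1; z* ≡ 0 (interaction in the
nuisance span) → explicit error rather than a meaningless p-value;
enumeration budgets exceeded → error advising the Monte-Carlo engine.
Problem sizes in the validation suite (50 oracle datasets at N = 10⁵, 2000
null simulations at N = 999, 200-simulation power points) were chosen as
the smallest runs that pin each property to useful precision.

## Known limitations

- **Finite-sample conservatism of the synergy test.** Measured over 2000
  null simulations at the default study conditions (8 embryos per genotype,
  12 hemisegments each), the rejection rate at α = 0.05 is ≈ 0.018 — valid
  but conservative. Two causes, both intrinsic to the published procedure
  rather than to this implementation (the vectorised statistic matches
  explicit per-permutation re-fits to 10⁻¹⁶): (i) the no-intercept model
  leaves z* with a nonzero column sum, so the permutation distribution of
  the raw coefficient carries a random location offset (a t-statistic
  variant does not cure it, measured ≈ 0.033 with continuous Gaussian
  responses); (ii) granular proportion responses create ties, which the
  ≥-counting rule scores conservatively. Power is correspondingly reduced
  at small effect sizes; the test never over-rejects.
- One defect category per generated hemisegment; real data may contain
  co-occurring defects, which the classifier handles but the round-trip
  guarantee does not cover.
- No asymptotic (t/F) p-values are exposed; no multiple-testing correction
  is applied across the three categories, matching the reporting
  convention the pipeline mirrors.
- The comparative-Ct module assumes perfect doubling per cycle; primer
  efficiency estimation and standard curves are out of scope.
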