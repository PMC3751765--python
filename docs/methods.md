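# Methods

## The model

`ahpgroup` implements a group analytic hierarchy process (AHP) for
stated-preference studies in which several stakeholder groups judge a set of
alternatives against a common baseline under a tree of decision criteria.

**Priorities from pairwise comparisons.** Each respondent compares items
pairwise on the bipolar 9–1–9 instrument: a judgment *(favored, score)*
decodes to the ratio `a_lr = score` (left favored), `1/score` (right
favored) or `1` (neither, only legal with score 1). A complete set of
judgments over one sibling set forms a positive reciprocal matrix
`A` (`a_ii = 1`, `a_ij·a_ji = 1`). The priority vector is the principal
right eigenvector of `A`, normalized to unit sum; Perron–Frobenius
guarantees it exists, is unique, and is strictly positive. We compute it by
power iteration from the uniform vector (convergence when successive
normalized iterates differ by < 1e-12 in max norm; bounded at 10 000
iterations, which is defensive only since the iteration always converges for
positive matrices). `lambda_max` is estimated as the mean of the
component-wise Rayleigh ratios `(A w)_i / w_i` at convergence — exact for
consistent matrices and stable near consistency.

**Consistency.** CI = (lambda_max − n)/(n − 1) ≥ 0, zero iff the matrix is
transitive; CR = CI/RI with Saaty's classical random-index table (0, 0,
0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49 for n = 1…10). CR is defined
as 0 when RI = 0 (n ≤ 2). The acceptability threshold defaults to the
conventional 0.10 but is configurable, and exceeding it produces a warning
in reports rather than an error: group-level panels with CR up to ~0.15 are
routinely interpreted in applied work, and the pipeline should never
silently discard a stakeholder group for moderate inconsistency.

**The star design.** The innovation block compares each of the m
alternatives only against the "current care" hub, one judgment per
alternative per leaf criterion. The implied (m+1)×(m+1) matrix is completed
by transitivity through the hub (`a_ij = a_i0/a_j0`), is rank-one consistent
by construction (CR ≡ 0), and its eigenvector has the closed form: hub
weight `1/(1 + Σ a_i0)`, alternative i weight `a_i0/(1 + Σ a_i0)`. The
closed form is used in the pipeline; equality with power iteration on the
completed matrix is enforced in tests. Because the completed block is always
consistent, per-respondent CR is informative only for the criteria block.
Incomplete sibling comparisons are rejected, not imputed: no completion rule
(e.g. Harker's) is defensible without knowing why a judgment is missing.

**Group aggregation (AIJ).** "The group's judgment" is the entrywise
geometric mean of the individual matrices — the standard aggregation of
individual judgments, chosen because it preserves reciprocity exactly and is
invariant under duplicating the panel. An entrywise arithmetic mean (upper
triangle averaged, reciprocity then restored) is available as a sensitivity
option. Aggregation happens at the judgment level, with one eigenvector per
group; per-respondent priority vectors are still computed for the dispersion
and bootstrap analyses.

**Hierarchical synthesis.** Local sibling weights propagate multiplicatively
down the tree (global leaf weight = product of local weights on the root
path; a childless main criterion is its own leaf). The overall priority of
an alternative is the weighted sum of its per-leaf priorities with the
global leaf weights. The baseline stays inside the normalization, so every
priority column includes a baseline row summing into the 1.0 total; a
renormalized no-baseline view is an output option.

## The shipped study configuration

The default hierarchy has four main criteria — efficiency (split into
patient self-management and efficiency of organization), health gain,
satisfaction (health care professionals / patients), investments (initial /
restructuring) — i.e. seven leaves. Six stakeholder groups are configured:
patients (15), nurses (22), physicians (9), managers (9), health insurers
(5), policy makers (6). (The study this configuration mirrors reports a
total of 62 respondents in its text while its per-group counts sum to 66;
the per-group counts are used.) A complete criteria block needs 6 main-pair
plus 3 sub-pair judgments; the source study describes seven criteria
comparisons, which cannot cover the complete design — the package uses the
complete 9-judgment design and treats anything less as incomplete. The
innovation block is 9 innovations × 7 leaves = 63 judgments, matching the
source design exactly.

## The synthetic-data generator

The generator emulates the elicitation: for every respondent it draws each
criteria-pair judgment from the group's true local weight ratio `w_a/w_b`
and each star judgment from the group's true innovation-vs-baseline ratio,
perturbing each independently. Noise is multiplicative log-normal on the
elicited magnitude `max(r, 1/r)` — the natural error model on a ratio scale
— with the favored side reattached afterwards, which makes perturbation of
`x` and `1/x` under the same random stream exactly reciprocal. With
`discretize=True` (default) the perturbed ratio snaps to the nearest
instrument value in log space (1–9 and reciprocals) and the survey
round-trips through the CSV format; with `discretize=False` judgments keep
continuous ratios truncated at the instrument extremes [1/9, 9] and exist
in memory only.

`noise_sigma` defaults to 0.3: under the default scenario this yields
individual 4×4 criteria-block consistency ratios with median ≈ 0.03 and
upper range ≈ 0.15, the range reported for comparable stakeholder panels.
The truth of the default scenario is the reference study's printed group
weights and overall priorities (read at two decimals, renormalized exactly).
Only overall priorities were published, so the same
innovation-vs-baseline ratio vector is used under every leaf criterion; the
overall truth then equals the published column regardless of criterion
weights. This is a fixture choice for realism of scale and ordering, not a
claim of reconstructing the raw survey. No respondent-level bias, dropout or
attention failure is modeled: passing recovery tests demonstrate internal
consistency of the pipeline under independent log-normal noise, not
robustness to the systematic response styles real panels can exhibit.

## Uncertainty

The source study states 95% CIs without describing their construction. The
package's intervals are nonparametric percentile bootstrap over respondents
(default B = 10 000): resample the group's respondents with replacement,
rerun the entire AIJ pipeline per replicate. This is an assumption-light
reconstruction — an interpretation, not a replication. Within-group
comparisons of two innovations are paired (both use the same resample
schedule, enforced via a shared seed); between-group comparisons resample
independently. A difference is flagged significant when its percentile
interval excludes 0; no multiple-testing correction is applied by default
(a Bonferroni factor for the 9-innovation family can be applied by the
caller via the `level` argument). Box-plot summaries of individual overall
priorities use linear-interpolation quartiles and 1.5×IQR whiskers.

The bootstrap coverage property is verified in the test suite on continuous
(non-discretized) simulations, where the ground truth equals the estimand of
geometric-mean aggregation; under discretization the estimand acquires a
small snap-to-scale bias that is a property of the instrument, not of the
interval construction. The suite uses 200 panels of n = 20 at sigma = 0.3
with B = 300 and accepts coverage ≥ 0.885 (nominal 0.95 minus four binomial
standard errors at 200 repetitions).

## Numerical choices and conventions

- Internal normalization tolerance is 1e-9; tables transcribed at two
  decimals are validated at 0.02 (ten rounded entries can drift the column
  sum by up to 0.05, but sibling sets have at most four).
- Table output rounds half away from zero at two decimals, mirroring the
  reference tables' formatting.
- Negative CI from floating-point `lambda_max` on exactly consistent input
  is clipped to 0.
- Leaf and item order is fixed by the configuration (depth-first for
  criteria; baseline first for the innovation block), making report files
  bit-identical across runs on identical input.
- Scale values are the integers 1–9 only; no intermediate fractions are
  offered by the instrument emulated here.
- Respondents with incomplete designs are excluded with a logged warning by
  default (`on_incomplete="error"` to fail hard); respondents are never
  excluded for high individual inconsistency.
- Rank agreement counts a pair tied in exactly one vector as 0.5 and tied in
  both as full agreement, so identical vectors always score 1 even when the
  truth itself has tied priorities.

## Problem sizes

Default simulated studies are the full 66-respondent scenario (4 752
judgments); unit fixtures use 6–14 respondents. Bootstrap defaults to
B = 10 000 in the API; the test suite and acceptance script use B in the
hundreds to low thousands, which is ample for 95% percentile endpoints of
the smooth statistics involved.

## Known limitations

- Networked (non-tree) criteria structures are out of scope, as are fuzzy or
  interval judgments.
- The arithmetic aggregation option breaks the star block's exact
  consistency; it exists for sensitivity analysis only.
- No consistency-repair algorithms: inconsistent input is reported, never
  modified.
- The generator's truth reuses one ratio vector across leaves, so simulated
  per-leaf priorities are less heterogeneous than a real panel's.
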