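# ahpgroup

Group analytic hierarchy process (AHP) for stakeholder preference studies.

Health-care decision makers often disagree about which innovation to adopt
first because costs and benefits fall on different shoulders. One way to
quantify that disagreement is to have each stakeholder group judge a set of
innovations pairwise against current care under a tree of decision criteria,
and derive ratio-scale priorities per group. `ahpgroup` implements that
pipeline end to end for analysts running such studies:

- **hierarchy** — criteria trees, validation, propagation of local sibling
  weights to global leaf weights;
- **judgments** — the bipolar 9–1–9 survey scale, long-format CSV ingestion,
  reciprocal pairwise matrices, and the star (hub) design in which every
  innovation is compared only against a baseline;
- **priority_engine** — principal-right-eigenvector priorities by power
  iteration, consistency index/ratio with Saaty's random-index table, and
  the closed form for star designs;
- **group_synthesis** — geometric-mean aggregation of individual judgments
  (AIJ), per-group weights and priorities, weighted-sum synthesis, JSON/CSV
  reports;
- **uncertainty** — per-respondent priorities, box-plot dispersion
  summaries, and percentile-bootstrap confidence intervals over respondents;
- **synthetic_data** — a study simulator with known ground truth
  (multiplicative log-normal judgment noise, optional snap to the discrete
  1–9 scale) so every stage is testable without access to raw survey data.

## The model in brief

For items compared pairwise on a ratio scale, the judgment matrix
`A = (a_ij)` is positive and reciprocal (`a_ij a_ji = 1`). Priorities `w`
solve `A w = λ_max w` (principal right eigenvector, unit sum). Inconsistency
is measured by `CI = (λ_max − n)/(n − 1)` and `CR = CI / RI_n`. Local
weights multiply down the criteria tree to global leaf weights `w_ℓ`, and
the overall priority of innovation `i` is `p_i = Σ_ℓ w_ℓ · p_{i|ℓ}`. Groups
are aggregated by the entrywise geometric mean of their members' matrices
before deriving one eigenvector per group. See `docs/methods.md` for the
full account.

## Worked example

```python
import ahpgroup as ag
from ahpgroup import datasets, synthetic_data

h = datasets.hospital_it_hierarchy()          # 4 main criteria, 7 leaves
study = synthetic_data.simulate_study(synthetic_data.default_config(seed=1))
result = ag.run_study(study.respondents, study.judgments, h)

print(result.priority_table(rounded=True)[["patients", "policy makers"]])
cr = result.groups["policy makers"].consistency["criteria:goal"]
print(f"policy makers main-criteria CR: {cr.cr:.3f}  acceptable: {cr.acceptable}")
```

Output:

```
                         patients  policy makers
current_care                 0.05           0.05
Virtual consultation         0.08           0.09
Digital hospital portal      0.10           0.12
Planning operations          0.12           0.11
Telepathology                0.08           0.08
Barcodes                     0.16           0.13
PDA                          0.09           0.10
Telesurgery                  0.08           0.06
Regional EPF                 0.15           0.10
Self-tests                   0.09           0.17
policy makers main-criteria CR: 0.003  acceptable: True
```

Each column is one stakeholder group's overall priority vector: it sums to
1 across the nine innovations plus the current-care baseline, and a larger
value means a stronger preference. Here patients put the most weight on
medication barcodes (0.16) while policy makers favor self-tests (0.17) —
the two groups disagree sharply about the same innovation. The consistency
ratio 0.003 says the aggregated policy-maker judgments are highly
transitive (0 is perfect; ≤ 0.10 is conventionally acceptable).

Bootstrap uncertainty for one group:

```python
from ahpgroup import bootstrap_group, compare

boot = bootstrap_group(study.respondents, study.judgments, h,
                       "policy makers", b=1000, seed=2)
r = boot["Self-tests"]
print(f"Self-tests: {r.estimate:.3f}  95% CI [{r.ci_low:.3f}, {r.ci_high:.3f}]")
d = compare(boot["Self-tests"], boot["Telesurgery"], paired=True)
print(f"vs Telesurgery: gap {d.estimate:.3f}, significant: {d.significant}")
```

```
Self-tests: 0.165  95% CI [0.150, 0.181]
vs Telesurgery: gap 0.108, significant: True
```

The same pipeline is available from the shell:

```bash
ahpgroup simulate --out-survey survey.csv --seed 1
ahpgroup run --survey survey.csv --out-json report.json --priorities-csv table.csv
ahpgroup bootstrap --survey survey.csv --group "policy makers" --reps 1000 --seed 2
```

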