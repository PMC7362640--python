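# upcode-screen

Unsupervised screening for **DRG upcoding** among hospitals, built on
administrative hospital-discharge data.

Upcoding is the practice of registering diagnosis/procedure codes so that a
hospitalization falls into a better-reimbursed DRG — typically the "with
complications" (CC) member of a CC/non-CC DRG pair. Evident outliers (extreme
volumes, extreme billing) are easy to catch; this package targets the
*cautious* deviant: a provider whose coding style drifts from that of its
otherwise-similar peers without being extreme on any single dimension.

The pipeline is a two-step method over a disease-specific cohort (heart
failure by default, configurable to any disease):

**Step One — local outlier screening.**
Each provider *h* is described by a behavioral feature vector: the relative
frequencies *r<sub>ih</sub>* with which it codes each disease-related DRG
*i*, plus scalar indexes (average cost, average LOS, volume, specialization,
CC share, upcoding index, average cost per patient). After z-scoring:

1. *Ensemble Principal Feature Analysis* — PFA clusters the features'
   principal-component loading rows and keeps one representative feature per
   cluster; because the inner k-means is greedy, the selection is repeated
   B = 200 times and the *n* most frequently chosen features are kept.
2. *Grid search* — for every pair (n, k) in {20, 30, 40} x {5, 6, 7, 8},
   cluster providers with k-means and score the partition by average
   silhouette width; the silhouette-maximizing pair wins.
3. *Flagging* — each provider's Euclidean distance to its own cluster
   centroid is computed; providers strictly above the 95th percentile of the
   distance distribution are flagged. With N distinct distances this flags
   exactly N − floor(1 + 0.95(N − 1)) providers — 10 of 183.

**Step Two — auditor decision support.**
For each flagged provider: its percentile position (strict rank / N) on five
fraud-related variables (average cost, CC share, specialization, number of
visits, upcoding index), and a casemix cross-validation comparing its
patients against the whole population on log-scale age, LOS, comorbidity,
total cost, cost/LOS and cost/comorbidity. The output is descriptive — a
provider with long stays and ordinary cost-per-complexity probably just
treats sicker patients; short stays with inflated cost-per-complexity are
worth an auditor's time. No verdicts are produced.

A synthetic-claims generator (`upcode_screen.synthetic_data`) emulates the
structure of a regional discharge database — hospital behavior archetypes,
per-patient comorbidity/LOS/cost models, CC-paired DRGs — and plants known
deviants (upcoders that relabel non-CC episodes with probability δ, and
complex-casemix providers), so the whole pipeline is testable end to end
with ground truth.

## Worked example

```python
from upcode_screen import (
    SimConfig, GridConfig, PFAConfig, WeightTable,
    simulate, extract_cohort, build_patients, build_hospitals,
    screen, fraud_dashboard,
)
from upcode_screen.synthetic_data import default_cohort_config

config = SimConfig(seed=1, n_planted_upcoders=10, n_planted_complex=0)
records, truth = simulate(config)                      # ~37k hospitalizations
cohort = extract_cohort(records, default_cohort_config(config))
weights = WeightTable.load_default()
patients = build_patients(cohort, weights)
profiles, matrix = build_hospitals(cohort, patients, weights)

result = screen(matrix, GridConfig(seed=1, pfa=PFAConfig(n_select=20, n_runs=200)))
print(result.best_n, result.best_k, round(result.silhouette_mean, 3))
print(len(result.outlier_ids), sorted(set(result.outlier_ids) & truth.upcoders))
```

prints

```
40 6 0.422
10 ['H067', 'H090', 'H107', 'H113', 'H135', 'H136', 'H150', 'H163', 'H181']
```

i.e. the grid search keeps 40 features and finds the 6 planted behavior
groups; of the 10 providers flagged at the 95th percentile, 9 are planted
upcoders. The dashboard then locates each flagged provider within the
population:

```python
table = fraud_dashboard(profiles, result.outlier_ids[:1])
print(table.round(3))
```

```
                 H067
avg_cost        0.350
pct_cc          0.934
specialization  0.661
n_visits        0.322
upcoding_index  0.934
```

H067 sits above the 93rd percentile on CC share and upcoding index while
being unremarkable on cost, volume and specialization — the signature of a
cautious upcoder rather than an evident outlier.

The same flow is available from the shell:

```bash
upcode-screen simulate --seed 1 --out synth/
upcode-screen extract --in synth/hdc.csv --config synth/cohort_config.json --out cohort/
upcode-screen screen --cohort cohort/ --seed 1 --out result/
upcode-screen audit --cohort cohort/ --result result/ --out audit/
```

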