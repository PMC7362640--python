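# Methods

## The screening model

The unit of analysis is the *provider*, described by behavioral features
derived from the hospital discharge charts (HDCs) of a disease-specific
cohort. A patient enters the cohort when at least one in-window discharge
carries an index-disease diagnosis code (prefix match, any position); all
in-window discharges of cohort patients are kept, so that the denominator of
the specialization ratio (disease episodes / all visits) reflects the
provider's full activity.

The working hypothesis is behavioral: providers of similar size, role and
casemix should code similarly. A deviant coder is therefore sought *locally*
— as a point unusually far from the centroid of its own peer cluster —
rather than globally. This deliberately targets the cautious deviant who
would not show up in any marginal distribution.

### Feature construction

Per provider: the DRG-mix vector `r` (relative frequency of each
disease-family DRG among the provider's disease episodes; a point on the
probability simplex), and eight scalars — average cost and average LOS per
visit, disease-episode count, visit count, specialization, CC share among
disease episodes, upcoding index, and average cost per patient.

The **upcoding index** here is the provider's CC share among disease-family
episodes divided by the population's CC share: 1 is population-typical
coding, above 1 a CC-heavier style. It is a deliberately simple, scale-free
operationalization of the upcoding-tendency construct, isolated in one
function (`aggregation.upcoding_index`) so an alternative formula can be
swapped in.

The **comorbidity index** is the combined comorbidity score (Gagne et al.
2011): a weighted count of distinct coded conditions, each counting once per
discharge, summed per patient across discharges with no per-admission
normalization. The condition/weight/prefix table ships as editable YAML.

All columns are z-scored before any distance-based step; constant columns
are dropped with a warning. Euclidean methods on mixed-unit features
(currency, days, counts, fractions) are meaningless without this.

### Feature selection: ensemble PFA

Principal Feature Analysis represents each feature by its loading row on the
q leading principal components (q = smallest dimension retaining >= 90% of
variance, configurable), clusters the rows with k-means into n groups, and
keeps the feature closest to each group mean. Redundant features have nearly
identical loading rows and collapse into one representative.

A single PFA run inherits the greedy instability of its inner k-means
(random initialization, 10 restarts per run). The ensemble therefore repeats
the run B = 200 times with seeds derived from one master seed, counts how
often each feature is selected, and keeps the n most frequent, ties broken
by (higher count, then lexicographic name). Loading rows are clustered in
canonical (sorted-name) order and representative ties are broken by name
after rounding distances at 1e-10, which makes the output invariant to the
column order of the input matrix.

### Model selection and flagging

For every (n, k) in the grid (defaults {20, 30, 40} x {5, 6, 7, 8}), the
pipeline selects n features by ensemble PFA, fits k-means (k-means++ with 10
restarts, per-cell derived seeds), and scores the partition by the average
silhouette width s(i) = (b−a)/max(a,b) with Euclidean distances; singleton
clusters contribute s = 0, and a degenerate fit (fewer than k non-empty
clusters after one re-seed) skips the cell with a warning. The
silhouette-maximizing cell wins; exact ties prefer smaller k, then smaller
n. Feature selection can be skipped entirely (`use_feature_selection=False`),
the robustness variant.

Local distances are Euclidean distances to the assigned centroid, computed
in the same standardized selected-feature space the clustering ran in. The
flagging threshold is the 95th percentile of the distance distribution under
the linear-interpolation convention, with *strictly greater* flagging. This
pair of conventions is load-bearing: with N distinct distances it flags
exactly N − floor(1 + 0.95(N − 1)) providers — 10 of 183, 5 of 100 — and
flags nothing when all distances are equal.

### Audit step

Percentile positions in the dashboard use the strict-rank convention
(count of population values strictly below, divided by N), which maps the
population minimum to 0 and the maximum of N distinct values to (N−1)/N —
0.994 (truncated to three decimals) at N = 183.

Casemix comparisons are made on log(x + 1), since LOS and comorbidity are
legitimately 0; cost/LOS treats same-day discharges as one day, and
cost/comorbidity divides by (comorbidity + 1) with the per-discharge score
clipped at 0 (the combined score can be negative; the comparison tracks
burden). HDC-level variables (LOS, comorbidity, cost ratios) attribute each
discharge to the treating hospital; patient-level variables (age, total
cost) use the patients with at least one discharge there, so a patient seen
by two providers informs both comparisons without being double-counted
within either. Outputs are means and quartiles of both distributions plus
density plots; no classification is attempted.

## The synthetic-data generator

The generator emulates a three-year regional extraction around one disease,
scaled down in event count (~37k events vs. hundreds of thousands) so the
full pipeline runs in seconds:

- **183 hospitals in 6 archetype groups** (round-robin assignment). Groups
  differ in DRG mix (each group concentrates 60% of its mix on its own
  disjoint block of 3 DRG pairs, Dirichlet concentration 400 around the
  archetype), base CC probability (0.15 -> 0.35 across groups, hospital-level
  jitter sd 0.04), base LOS (5 -> 10 days), specialization (0.55 -> 0.30) and
  tariff level (pair tariffs grow 6% per pair index, so mix implies cost).
- **Patients**: age ~ Normal(76, 10) truncated to [18, 105]; coded
  comorbid conditions ~ Poisson with an age-increasing rate, drawn from the
  shipped weight table's prefixes; 1 + Poisson(0.5) disease episodes each,
  plus non-disease visits at a rate set by the group's specialization; 5% of
  non-disease visits occur at another hospital.
- **Episodes**: DRG pair from the hospital's mix; CC with the hospital's
  probability; LOS ~ lognormal with a comorbidity-increasing location;
  cost = pair tariff x (1 + 35% CC premium) x hospital multiplier x
  lognormal noise.
- **Planted upcoders** relabel each non-CC disease episode to its CC pair
  with probability delta (default 0.4) — and receive the CC tariff — but are
  otherwise identical to their group: no volume or casemix anomaly. Expected
  CC share is p + delta(1 − p). Optional knobs widen per-fraudster intensity
  (`delta_spread`) or restrict gaming to a random subset of DRG pairs
  (`target_pair_frac`); both default to off.
- **Planted complex-casemix providers** have 1.8x comorbidity rates and
  1.5x base LOS — the benign explanation Step Two should surface.

Deviants are planted round-robin across groups. Hospital volumes use a
tight lognormal spread (cv 0.06) rather than Poisson counts: volume is a
stable institutional characteristic, and this keeps the volume columns
informative about archetypes instead of a noise source.

Default deviants are 8 upcoders + 2 complex providers; the end-to-end
recovery experiments use 10 upcoders and no complex providers so that every
planted deviant is of the "cautious fraudster" type being scored.

### Calibration of the deviation scale

The defaults place a planted upcoder's distance-to-centroid just above the
95th percentile of the natural distance distribution (roughly 6 vs. 5 in
standardized units). This window is deliberate, and both edges matter: a
much larger shift makes the deviants so distant that the silhouette
criterion prefers giving them their own (k+1)-th cluster — at which point
they stop being local outliers and recovery of both k and the deviants
collapses — while a smaller shift loses them among ordinary sampling noise.
The cautious-fraudster construct is exactly this regime, and the generator
realizes it with the minimum relabeling probability (0.4) rather than a
dramatic one.

### What the generator does not model

Real tariff schedules or ICD code frequencies; temporal drift within the
window; coder-level error (all deviation is hospital-level and
directional); patient selection or transfers between specific hospitals;
correlation between ownership and behavior. Passing recovery tests
therefore shows the pipeline detects coding-style shifts of the modeled
kind and size under clean group structure — not that it would achieve the
same recall on real claims, where group structure is weaker and deviance
multi-causal.

## Numerical and design choices

- Window membership is judged on admission date, inclusive on both ends.
- LOS is the whole-day date difference; 0 is valid and treated as 1 only in
  ratio denominators.
- All diagnosis positions are scanned both for cohort qualification and for
  comorbidity scoring.
- "Number of visits" counts hospitalizations, not unique patients (a
  distinct `n_patients` is kept on each profile).
- Average cost divides by visits (all activity), average cost per patient by
  distinct patients.
- Hospitals with zero disease-family episodes are excluded with a warning;
  a population with zero CC episodes makes the upcoding index undefined and
  raises.
- Grid-cell and PFA-run seeds derive from the master seed via
  `numpy.random.SeedSequence` spawn keys, so results are independent of
  evaluation order and reproducible bit-for-bit.
- Problem sizes in the test suite (183 hospitals, ~37k events, B = 50 over
  10 seeds for the recovery experiment; B = 200 elsewhere) were chosen to
  keep the full suite at desk scale — under a minute for the unit tests and
  a few minutes for the recovery experiment.

## Known limitations

- The upcoding index is a stand-in ratio, not a validated audit statistic.
- The silhouette criterion can, in principle, spend a cluster on a tight
  clique of co-deviating providers; the screening then reports them as a
  (suspicious) cluster rather than as outliers. Inspecting small winning
  clusters is advisable in practice.
- Percentile flagging fixes the *share* of flagged providers (~5%), not an
  absolute deviation scale; on a population with no deviants it still flags
  the top 5%.
- The casemix comparison is descriptive; it does not adjust for casemix in
  the indexes themselves (no risk-adjusted expected costs).
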