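# airwaycrowd

Tools for analyzing crowdsourced airway annotations in chest CT.

## The problem

Airway wall thickening is a marker of airway disease (e.g. cystic
fibrosis), quantified by outlining the lumen and the outer wall of an
airway in a CT cross-section. Outlining by trained observers is accurate
but slow; crowdsourcing distributes the drawing task — "place one ellipse
on the inner and one on the outer airway boundary" — to many untrained
workers and buys throughput at the price of noisy, partly unusable input.
Making that trade work requires three things this package implements:

1. **Filtering** — classify each submitted result as valid or invalid from
   its geometry alone (right number of ellipses, actually resized,
   overlapping), with separate accounting for multi-airway submissions and
   "no airway visible" markers.
2. **Combining** — aggregate the redundant valid results per task into one
   estimate (median of areas, a random single result, or the
   best-vs-reference result as an upper bound).
3. **Evaluation** — correlate crowd estimates against expert references,
   sweep the minimum-valid-results threshold, profile worker behavior, and
   test whether subject characteristics predict crowd quality.

A seeded synthetic generator produces full study-scale datasets (24
subjects, ~1000 tasks, 20 results per task, hundreds of workers with
heavy-tailed productivity and a mixture of careful and invalid-producing
behaviors), so every pipeline stage can be validated against known ground
truth.

## Measures

From inner and outer cross-sectional areas `a_i < a_o` (mm²):

| Measure | Definition |
|---|---|
| equivalent diameter | `d = 2·√(a/π)` |
| wall thickness | `WT = (d_o − d_i)/2` |
| wall thickness ratio | `WTR = WT / d_o` |
| wall area percentage | `WAP = (a_o − a_i)/a_o × 100` |

Diameters are equivalent-circle diameters computed from areas on both the
crowd and the expert side, since the expert reference records areas only.
For concentric circles `WAP = 100·(1 − (1 − 2·WTR)²)`, an identity the
test suite uses as an oracle. See `docs/methods.md` for the full methods
account.

## Worked example

Simulate a small study and run the full pipeline (filter → measure →
combine with every strategy → evaluate):

```python
from airwaycrowd import CrowdStudy
from airwaycrowd.synthetic import CohortConfig, CrowdConfig

study = CrowdStudy.from_simulation(
    seed=7,
    cohort_config=CohortConfig(n_subjects=6, tasks_per_subject=(20, 30)),
    crowd_config=CrowdConfig(n_workers=200, results_per_task=20),
)
res = study.fit()
print(res.summary())
```

Output:

```
Crowd airway annotation study
=================================
results: 3000  tasks: 150  workers: 200
valid: 1388 (46.3%)  invalid: 1514 (50.5%)  multi-pair: 98 (3.3%)
'no airway' markers: 311

Pearson correlations vs expert 1 (v=1):
measure   inner  outer    wap    wtr
strategy
best      0.997  0.998  0.814  0.819
median    0.994  0.993  0.499  0.509
none      0.878  0.829  0.225  0.221
random    0.970  0.951  0.273  0.301

Pearson correlations vs expert 2 (v=1):
measure   inner  outer    wap    wtr
strategy
best      0.994  0.992  0.592  0.596
expert_1  0.998  0.994  0.647  0.652
median    0.993  0.997  0.570  0.573
none      0.878  0.832  0.274  0.266
random    0.968  0.949  0.315  0.324

Quality prediction (Spearman, two-sided; adjusted alpha=0.01):
 characteristic  rho_s  p_value  significant_adjusted
         has_cf -0.207    0.694                 False
           fev1 -0.200    0.704                 False
            fvc  0.486    0.329                 False
      n_airways  0.174    0.742                 False
mean_generation  0.600    0.208                 False
```

The pattern to read off: area correlations are strong even for single
random results and near-perfect after median combining, while the
ratio-derived wall measures (WAP, WTR) are much noisier — combining and
the best-case bound lift them from weak toward moderate/strong. The same
analyses are available on real exported annotation tables via
`CrowdStudy.from_csv(...)` (see `airwaycrowd.io.PipelineConfig` for column
mapping and units).

`res` also exposes the underlying tables: `res.labels`, `res.measurements`,
`res.estimates[strategy]`, `res.correlations`, `res.worker_stats`,
`res.per_subject`, `res.quality`, plus `res.threshold_sweep(...)` and
`res.correlation_matrix(...)`.

## Command line

The same pipeline is scriptable as stages over CSV files:

```bash
airwaycrowd simulate --seed 7 --out-dir data/
airwaycrowd filter  --results data/results.csv --out labels.csv
airwaycrowd measure --results data/results.csv --labels labels.csv --out meas.csv
airwaycrowd combine --measurements meas.csv --strategy median --out est.csv
airwaycrowd report  --results data/results.csv --experts data/experts.csv \
    --tasks data/tasks.csv --subjects data/subjects.csv --out-dir report/
```

`report` writes every table, the summary text, and scatter/threshold-sweep
figures. All commands accept `--config config.yaml` for frame geometry,
validity thresholds, units and column mappings.

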