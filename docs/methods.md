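# Methods

## Problem and measures

Crowd workers outline an airway in a 500×500-pixel CT slice by drawing two
ellipses: one around the lumen (the open channel) and one around the outer
wall boundary. From the two areas `a_i < a_o` (mm²) the package derives

- equivalent-circle diameters `d = 2√(a/π)`,
- wall thickness `WT = (d_o − d_i)/2` (mm),
- wall thickness ratio `WTR = WT / d_o` (dimensionless, in [0, 0.5)),
- wall area percentage `WAP = (a_o − a_i)/a_o × 100`.

The reference expert records only areas, so crowd-vs-expert diameter
comparison must assume circular airways; the crowd's diameters are therefore
also computed as equivalent-circle diameters from areas, never from the
drawn major/minor axes, keeping both sides on the same footing. Because WTR
and WAP are scale-free, the pixel-to-mm conversion (default 0.05508 mm/px,
i.e. 0.5508 mm voxels at 10× upsampling) cannot change any correlation
reported downstream; a test asserts this invariance.

For concentric circles the two wall measures are algebraically linked,
`WAP = 100·(1 − (1 − 2·WTR)²)`, which the test suite uses as a cross-check.

## Validity filtering

A result is kept only when it is exactly two resized, overlapping ellipses.
The classifier applies rules in a fixed order; every result gets exactly one
label:

1. ≥ 4 annotations → `multi_pair` (excluded as its own category, since
   multi-pair submissions are accounted separately from ordinary invalids;
   3 annotations are a wrong count, not a pair and a half);
2. count ≠ 2 → invalid `wrong_ellipse_count`; a single small circle in the
   top-right corner of the frame additionally carries the "no airway
   visible" flag;
3. an unresized default tool circle → invalid `not_resized`. One unresized
   ellipse already spoils the pair: a default circle carries no measurement,
   so requiring both to be default would let half-meaningless results
   through;
4. interiors that do not intersect with positive area → `not_overlapping`;
5. otherwise valid.

Numerical choices that the task definition leaves open, all exposed as
configuration:

- corner-marker region = top-right 20% × 20% of the frame, marker mean
  semi-axis < 10% of frame width;
- default tool size 50 px, recognized within 2% relative tolerance (both
  semi-axes within tolerance of the default, which also forces
  near-circularity);
- the overlap predicate discretizes each ellipse boundary to a 256-vertex
  polygon and intersects polygons (shapely). Exact conic–conic intersection
  is deliberately avoided: genuine annotations are far from tangency, and a
  property test shows agreement with a rejection-sampling oracle except for
  sliver intersections below 10 px².

Degenerate valid pairs (exactly equal areas) are rejected rather than
ordered arbitrarily; the smaller-area ellipse is otherwise taken as the
lumen, since the interface does not label the two ellipses.

## Combining redundant results

Per task, valid results are aggregated by one of three strategies: the
element-wise **median** of inner and outer areas with WT/WTR/WAP recomputed
from the medians (never median-of-ratios), a seeded uniform **random**
single result (pessimistic single-worker proxy), or the **best** result —
closest to the expert in (inner area, outer area) Euclidean distance — as an
optimistic upper bound that peeks at the reference. Ties in "best" break
toward the smallest result id. The random strategy uses one seeded stream
per dataset and visits tasks in sorted task-id order with each task's rows
sorted by result id, so output is independent of input row order. Tasks with
fewer than `v` valid results can be excluded (`filter_min_valid`); tasks
with none produce no estimate.

## Evaluation

Crowd-vs-expert agreement is Pearson's ρ per measure, strategy and expert,
banded weak [0, 0.3), moderate [0.3, 0.5), strong [0.5, 1]; an undefined
coefficient (constant input) is reported missing, never zero. The "none"
strategy pairs each individual valid result with its task's expert value.
Expert-vs-expert rows are produced whenever more than one expert is present.
The threshold sweep reports median-combined ρ and the retained task count as
`v` rises.

Subject-level quality prediction uses the per-subject crowd-vs-expert inner
area correlation (median combining) as the quality proxy, and tests its rank
association with five characteristics — CF status, FEV1, FVC, airway count,
mean airway generation — by Spearman correlation with average ranks for ties
(binary CF enters through tied ranks). The two-sided p-value uses the
t-approximation `t = ρ_s√((n−2)/(1−ρ_s²))` on n−2 degrees of freedom, which
a test shows is calibrated at n = 24 (type-I error within [0.03, 0.07] at
nominal 0.05 over 2000 null replicates) and matches `scipy.stats.spearmanr`.
With five comparisons, the Bonferroni-adjusted threshold is 0.05/5 = 0.01.
Exact-permutation p-values were considered and not implemented: at n = 24
the t-approximation is adequate and is the cheaper, standard route.

Per-worker statistics tally valid/invalid/multi-pair counts, the cumulative
output curve over workers sorted by productivity, and an ordinary
least-squares fit of valid against invalid counts across workers.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not CT pixels:

- **Cohort** — 24 subjects by default, tasks per subject uniform on 20–66
  (≈ 1030 tasks in total); inner radii log-normal (median 1.4 mm, σ = 0.4,
  spanning several airway generations); wall thickness = lumen radius ×
  N(0.30, 0.05) clipped to (0.05, 0.95), which keeps the implied WTR in
  (0, 0.5) by construction; drawn-ellipse axis ratio uniform on [0.8, 1]
  (nearly circular, as for perpendicular cuts); task difficulty Beta(2, 2),
  optionally shifted by CF status (`difficulty_effect`, zero by default so
  no subject-level effect is planted).
- **Workers** — 577 by default with log-normal productivity (σ = 1.3);
  20 distinct workers per task drawn with probability proportional to
  productivity, giving the heavy-tailed per-worker output of real crowds.
  Behaviors (careful 43%, no-airway-prone 12%, non-resizer 16%,
  sloppy-single 14%, spammer 15%) are assigned over workers ranked by
  productivity with a largest-deficit quota rule, so every productivity
  stratum carries the configured mixture; with an i.i.d. assignment the
  productivity-weighted behavior shares — and hence the realized valid
  fraction — would swing by several points from seed to seed. The default
  mixture puts the valid share in the low forties and the multi-pair share
  near 3% (spam submissions draw 1–5 ellipses; the ≥ 4 tail is 20% of 15%).
- **Noise model** — careful workers redraw the true ellipses with
  multiplicative log-normal radius error (mean scale 10% across workers)
  and a few pixels of center jitter. Multiplicative-on-radii rather than
  additive-on-areas is the natural model for an outlining task and lets the
  extra noise in WAP/WTR emerge from the geometry. Difficulty modulates only
  the probability that a no-airway-prone worker posts the corner marker
  (0.8 + 0.2·difficulty), not the noise, reflecting the working hypothesis
  that tasks accumulating more valid results are simply easier.
- **Experts** — per task and expert, independent multiplicative log-normal
  area noise (5% default); two experts by default so the expert-vs-expert
  row exists.

What the generator does **not** emulate: image appearance (contrast, partial
walls, neighboring vessels), worker learning or fatigue over time, and any
correlation between a worker's productivity and behavior. Passing
recovery tests therefore demonstrate that the pipeline's filtering,
measurement and aggregation are correct and well-calibrated under the
assumed error structure — not that a real crowd would achieve the same
correlations.

## Problem sizes and seeds

The default simulated study is full scale (~1030 tasks × 20 results); the
test suite mostly runs a 24-subject cohort with 20–26 tasks per subject
(≈ 11 000 results), which keeps every stochastic check above 500 tasks while
the whole suite stays fast. All stochastic operations take explicit seeds;
a master seed spawns independent sub-streams (numpy `SeedSequence`), so a
single integer reproduces a study byte-for-byte.

## Known limitations

- The multi-pair rule (≥ 4 annotations) is a count heuristic; nested-pair
  grouping is not attempted.
- "Trying but not following instructions" is not a separate class; such
  results surface as invalid non-marker submissions.
- The overlap predicate is polygonal, so tangency within ~10 px² of
  intersection area may be classified either way.
- Expert references with inner ≥ outer area are rejected, not repaired.
- Real deposited annotation tables may need a column mapping (config
  `column_mapping`) and a units declaration (`area_unit`, `angle_unit`);
  the readers do not guess.
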