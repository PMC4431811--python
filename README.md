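# tracknest

Hierarchical statistical analysis of in-vivo lymphocyte motility tracks.

Two-photon microscopy yields 3D tracks of T cells migrating in lymph nodes.
Comparing the motility of two cell populations (say WT vs knockout) from such
tracks is statistically treacherous: the steps of one cell are not
independent observations, the fluorescent dyes used to label the populations
themselves alter motility and interact with cell type, and tracks are
collected in a nested design (imaging date → mouse → lymph node →
microscopic field → cell) whose blocks add further dependence.  Naive pooled
t-tests on step data are wildly anti-conservative, and unbalanced dye
assignment can even reverse the sign of an estimated population effect.

`tracknest` implements a ladder of analyses of increasing statistical
control, in sum-to-zero (effect) coding:

| rung | model |
|---|---|
| t-test | y<sub>ij</sub> = μ + α<sub>i</sub> + e<sub>ij</sub> |
| Mann–Whitney U | same comparison on ranks (exact U for small samples) |
| factorial ANOVA | y<sub>ij</sub> = μ + α<sub>i</sub> + β<sub>j</sub> + αβ<sub>ij</sub> + e<sub>ij</sub> (population α, dye β) |
| mixed-model ANOVA | adds a per-cell random intercept γ<sub>k</sub> ~ N(0, σ<sub>γ</sub>²) |
| nested ANOVA | adds random intercepts for date, mouse(date), node(mouse), field(node) above the cell |

Each parametric rung has a rank-transformed variant (Conover–Iman) giving
the nonparametric analogue; rank-scale estimates are mapped back to response
units through the inverse empirical quantile function.  Random-effect models
are fit by REML with Satterthwaite denominator degrees of freedom; levels
that are perfectly confounded with their child level (e.g. one mouse per
date) are detected and dropped with a logged notice.

The package also provides:

* **Track I/O** — long CSV tables (one row per position) with configurable
  column names and units, globally unique hierarchy IDs built by
  escape-safe label concatenation, and hierarchy validation/diagnosis.
* **Motility parameters** — step-based instantaneous speed (μm/min) and
  turning angle (degrees), cell-based per-track summaries, and the standard
  track filters (≥ 3 time steps, path length ≥ 17 μm, displacement² ≥ 300 μm²).
* **A simulator** — persistent-random-walk tracks in a 3D imaging box with
  log-normal speed hierarchy, von-Mises–Fisher turning persistence,
  configurable population/dye/interaction effects and boundary censoring,
  emitting ground truth for parameter-recovery and calibration studies.

## Worked example

Simulate an experiment shaped like a 5-day, 6-mouse, 7-node, 9-field study
with a small injected knockout slowdown (−0.04 on log speed) and a dye
confound, then run the full ladder:

```python
from tracknest import (paper_like_config, simulate_experiment,
                       run_pipeline, PipelineConfig, render_grid)

cfg = paper_like_config("pkc", seed=42, population_effect=-0.04,
                        dye_effect=0.03, interaction_effect=-0.03)
tracks, truth = simulate_experiment(cfg)
result = run_pipeline(tracks, PipelineConfig(responses=("speed",)))
print(render_grid(result.grids["speed"], "text"))
```

```
Analysis                                                     KO est.       WT est.       p-value
------------------------------------------------------------------------------------------------
t-test                                                          9.90          8.87       p<.0001
Mann-Whitney U test                                             8.94          8.24    p = 0.0014
Factorial ANOVA                                                 9.84          9.17    p = 0.0187
Factorial ANOVA, rank-transformed data                          8.79          8.59    p = 0.2186
Mixed model ANOVA controlling for cell IDs                     10.07          9.19    p = 0.3494
Mixed model ANOVA, rank-transformed data                        8.93          8.60    p = 0.5596
Nested ANOVA controlling for all experimental blocks           10.07          9.19    p = 0.3494
Nested ANOVA, rank-transformed data                             8.93          8.61    p = 0.5537
```

Reading the grid: the pooled t-test (thousands of correlated steps) reports
a wildly significant difference; once the dye terms and the per-cell random
effect absorb the confound and the step dependence, the evidence for a
population difference at this effect size and design is modest — the honest
answer for a small injected effect on 108 cells.  Estimates are per-
population marginal means in μm/min; the mixed rows sit above the pooled
rows because boundary censoring over-represents slow cells in pooled steps.
The matching effect table prints the signed sum-to-zero offsets (KO +0.34,
CFSE +0.45 μm/min here) with the reference arm recorded in metadata.

The same pipeline runs from the shell:

```sh
tracknest simulate --preset pkc --seed 42 --out tracks.csv --truth truth.json
tracknest validate tracks.csv
tracknest analyze tracks.csv --out-dir results/
```

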