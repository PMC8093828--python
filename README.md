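# ampdepth

**How few amplicon reads per sample can you sequence before a supervised
classifier stops matching its full-depth performance?**

`ampdepth` is a benchmarking toolkit for eDNA-metabarcoding surveys that
classify samples from ASV (amplicon sequence variant) community tables —
predicting biotic-index categories, impact zones, geographic origins,
production phases — with random forests.  Sequencing depth is a direct cost
driver, and rarefaction (the depth normalization RF pipelines require)
throws reads away anyway; knowing the minimum sufficient depth lets a survey
buy exactly the sequencing it needs.

Given a labelled count table, the package:

1. filters ASVs (< 50 total reads) and shallow samples (< 15,000 reads) and
   converts counts to relative abundances;
2. trains a **full model** grid — 7 `mtry` values around `floor(√p)` × 3
   repeat seeds = 21 random forests, 6000 trees each — scored by out-of-bag
   (OOB) error and by Cohen's kappa on the OOB predictions,
   `κ = (p_o − p_e)/(1 − p_e)`;
3. rarefies every sample without replacement down a 13-level depth ladder
   (shallowest sample, then 12,500 … 50 reads) and retrains the same grid
   at every level;
4. bands kappa — *almost perfect* (κ > 0.8), *moderate* (0.6 ≤ κ ≤ 0.8),
   *poor* (κ < 0.6) — and reports the **minimum depth** whose level still
   holds the full model's band (contiguously from the top of the ladder);
5. explains the result with separability diagnostics: Gini coefficient of
   class sizes, per-feature CV of class means, shared/exclusive feature
   fractions, and Bray–Curtis NMDS with per-class confidence-ellipse
   overlap.  Saturation is tracked by bias-corrected Chao1 coverage and
   exact hypergeometric rarefaction curves.

A synthetic-community generator (Dirichlet-multinomial with tunable class
effect size) makes the whole procedure testable end to end, including the
central qualitative claim: tasks with hard class boundaries stay in band at
far lower depths than tasks with soft boundaries.

## Worked example

A 30-sample, 330-ASV synthetic community with a *soft* class boundary
(class-specific ASVs only 3× enriched), swept with a reduced grid and
300-tree forests:

```python
from ampdepth import PipelineConfig, SyntheticSpec, generate_dataset, sweep_table

table = generate_dataset(SyntheticSpec(
    samples_per_class=(10, 10, 10),
    n_background_asvs=240, n_specific_asvs_per_class=30,
    effect_size=3.0, overdispersion=100.0,
    depth_range=(2_000, 4_000), seed=7,
))
config = PipelineConfig(
    min_asv_total=10, min_sample_depth=1_000, ladder_cap=2_000,
    n_trees=300, mtry_offset_range=1, n_runs=1, seed=7,
)
result = sweep_table(table, config)
print(result.decision.levels[["depth", "median_kappa", "mean_accuracy", "band"]]
      .to_string(index=False))
```

```
 depth  median_kappa  mean_accuracy           band
  2123          0.95       0.955556 almost_perfect
  1000          0.90       0.944444 almost_perfect
   500          0.90       0.922222 almost_perfect
   400          0.95       0.933333 almost_perfect
   300          0.90       0.911111 almost_perfect
   200          0.70       0.811111       moderate
   100          0.60       0.744444           poor
    50          0.50       0.700000           poor
benchmark: almost_perfect (kappa 0.95, accuracy 95.6%)
minimum sufficient depth: 300
```

The full-depth model classifies at κ = 0.95 (almost perfect agreement,
95.6% mean OOB accuracy).  Downsampling to 300 reads per sample keeps the
level's median kappa above 0.8; at 200 reads agreement drops to moderate —
so 300 reads is the minimum depth at which this task still delivers
full-data performance.  Rerunning with `effect_size=30` (hard boundaries)
drives the minimum down to 50 reads, and the diagnostics move accordingly
(median feature CV 0.77 → 1.5, mean ellipse overlap 0.04 → 0.00).

The same run from the shell:

```bash
ampdepth simulate --samples-per-class 10,10,10 --background-asvs 240 \
    --specific-asvs 30 --effect-size 3 --overdispersion 100 \
    --depth-min 2000 --depth-max 4000 --seed 7 --out sim/
ampdepth report --table sim/counts.tsv --metadata sim/metadata.tsv \
    --n-trees 300 --offsets 1 --runs 1 --ladder-cap 2000 \
    --min-asv-total 10 --min-sample-depth 1000 --seed 7 --out report/
```

which writes per-model records, per-level summaries, the depth decision and
the separability report (TSV/JSON), box-plot and ordination figures, and a
manifest with checksums — rerunning the same command reproduces every file
byte for byte.

## Layout

| module | contents |
| --- | --- |
| `ampdepth.tables` | `AsvTable` / `RelativeAbundanceTable` containers, TSV I/O |
| `ampdepth.synthetic` | Dirichlet-multinomial community generator |
| `ampdepth.preprocess` | ASV/sample filters, relative-abundance transform |
| `ampdepth.rarefaction` | depth ladder, hypergeometric downsampling, Chao1, curves |
| `ampdepth.sweep` | model grid, OOB training, kappa bands, depth decision |
| `ampdepth.diagnostics` | Gini, feature CV, Venn fractions, NMDS ellipse overlap |
| `ampdepth.pipeline` / `ampdepth.cli` | end-to-end runs, manifests, `ampdepth` command |

See `docs/methods.md` for the statistical details and design rationale.
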