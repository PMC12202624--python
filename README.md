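# reefcover

Benthic cover estimation and survey design for citizen-science reef
imagery.

Large-scale reef reconnaissance programs collect thousands of wide
field-of-view benthic photographs taken by untrained snorkellers, then
estimate coral cover from them using a segmentation model ("AI-alone")
and online volunteers who label the model's polygons ("AI + Citizen").
Before such data can inform management, three questions must be answered,
and this package implements the analysis chain that answers them:

1. **How accurate is each analysis method?** Per image *i* and coral
   category *j*, accuracy is the signed difference in percentage points
   of cover against trained expert analysis:

   *Accuracy_ij = Method_ij − Expert_ij*

   A per-category **best method** picks whichever of AI-alone or
   AI+Citizen has the smaller absolute mean difference over all images,
   and accuracy is also disaggregated into 10%-wide reef-state bins of
   expert cover.
2. **How many images per site, analysed by how many citizens, make a
   site estimate reliable?** Monte-Carlo resampling draws *n* images per
   run (and *m* analyses per image, with replacement) from the pooled
   accuracy library; a design is reliable when the run mean lands within
   ±5 pp in 95% of runs.
3. **How many images per site detect a real difference between sites?**
   Within-site standard deviations of best-method cover feed a
   two-sample t-test power analysis (effect 10 pp, power 0.8, α 0.05)
   per category and reef-state bin, solved via the noncentral-t
   distribution.

Covers themselves are computed from three annotation sources —
segmentation masks (pixel counting), expert polygons (area summing) and a
3×3 visual grid (equal 1/9 cell weights) — expressed as percent of
colonisable substrate (excluding water/sand/shadow), with multi-analyst
averaging. Because the validation imagery of such programs is typically
not public, a hierarchical synthetic-data generator
(reefs → sites → images → analysts, with configurable method biases,
noise and within-site heterogeneity) makes every stage testable against
known ground truth.

## Worked example

Run the whole pipeline on a small synthetic survey (30 sites × 20
images):

```python
import reefcover as rc

cfg = rc.PipelineConfig(
    generator=rc.GeneratorConfig(n_reefs=10, sites_per_reef=3, images_per_site=20),
    sim=rc.SimConfig(n_values=list(range(1, 41)), m_values=[1, 4], runs=2000),
    min_bin_images=30, seed=1, out_dir="out")
tables = rc.run_pipeline(cfg)
print(tables["summaries"].round(2).to_string(index=False))
```

```
   category  mean_diff   se  n_images  method
  branching      -0.14 0.24       600      ai
    massive      -1.49 0.22       600      ai
other_coral       7.17 0.25       600      ai
    plating      -6.19 0.22       600      ai
total_coral      -0.64 0.47       600      ai
  branching       9.17 0.23       600 citizen
    ...
total_coral       4.35 0.45       600    best
```

Reading the output: the simulated AI under-calls plating coral (−6.2 pp
vs the configured −9.1 pp population bias — compression toward zero is
expected because covers are bounded at 0) while citizens over-call
branching (+9.2 pp); the fused best method takes AI for branching and
citizen labels elsewhere, cutting the total-coral bias from −0.6/+13.7 to
+4.4 pp. `tables["min_images"]` then reports the smallest image count per
site meeting the ±5 pp / 95%-of-runs criterion for each analysis
multiplicity *m* (with `reached=False` where a category's accuracy never
meets it, as happens for the heterogeneous "other coral" group), and
`tables["power"]` lists the images per site needed to detect a 10 pp
cover difference given each bin's mean within-site SD.

The same pipeline is scriptable from the shell:

```bash
reefcover run-all --config examples/config.yaml --seed 1 --out-dir out
reefcover simulate-data --seed 1 --out-dir data        # covers.csv + truth.csv
reefcover accuracy --covers data/covers.csv --out-dir out
reefcover validate data/covers.csv
```

All outputs are 4-decimal CSV; a rerun with the same seed is
byte-identical, and `out/manifest.json` records the seed, config hash and
stage row counts.

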