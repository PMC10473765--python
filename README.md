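# neurocongruence

Cross-species comparison of volumetric sex differences in the human and
mouse brain, and of how that anatomical congruence relates to regional
transcriptional similarity.

Structural MRI studies find reproducible sex differences in regional brain
volume in both humans and mice, but the two literatures are rarely compared
quantitatively. This package implements that comparison as a tested,
reusable pipeline for researchers working with region-level volume tables
and expression matrices:

- **Standardized sex effects**: per region, the sex coefficient `b1` of an
  OLS fit to the z-scored volume, `z(vol) ~ 1 + b1*sex + b2*(age - mean age)
  + b3*TTV + b4*QC`, with QC exclusions, BH-FDR across regions, and Levene
  tests for sex differences in variance (female = reference, so `b1 > 0` is
  male-biased).
- **Cross-species congruence**: percentage-bend correlation (bend constant
  0.2) of human vs mouse `b1` across 60 homologous regions (28 bilateral +
  4 midline), overall and stratified by cortical/non-cortical compartment.
- **Similarity scores**: per region, the anatomical sex-effect similarity
  `b1_human * b1_mouse` (positive = congruent direction of sex bias) and the
  transcriptional similarity — Pearson correlation of the species' z-scored
  expression profiles across homologous genes.
- **Gene-subset nulls**: permutation p-values for subset-based similarity
  against 10,000 random gene sets of the same size.
- **Batch harmonization**: parametric empirical-Bayes location-scale
  adjustment of multi-cohort tables (validated against `sva::ComBat`).
- **Synthetic data**: seeded two-species cohort and expression simulators
  with known ground truth, so every stage is testable without subject data.

The published table of 60 paired effect sizes ships with the package, so the
headline congruence numbers can be recomputed with no external data.

## Worked example

Run the demonstration analysis on the bundled effect-size table:

```bash
neurocongruence demo-table1 --outdir demo_out
python - <<'PY'
import json
s = json.load(open("demo_out/summary.json"))
for comp, rec in s["congruence"].items():
    print(f"{comp:>14s}  r = {rec['r']:+.3f}  p = {rec['p']:.3f}  n = {rec['n']}")
PY
```

prints

```
           all  r = +0.298  p = 0.021  n = 60
      cortical  r = +0.218  p = 0.285  n = 26
  non_cortical  r = +0.175  p = 0.323  n = 34
```

i.e. a modest but significant cross-species correlation of regional sex
effects over all 60 homologous regions, and weaker non-significant
correlations within each compartment alone (the compartment split and how
it compares to the originally reported stratified values are discussed in
`docs/methods.md`). `demo_out/` also contains the pair table, per-region
similarity scores, and quadrant labels classifying each region as
congruently male-/female-biased or divergent between species.

The same machinery runs end-to-end on synthetic data:

```bash
neurocongruence simulate --outdir sim --seed 5 --n-regions 12 --n-genes 40
cat > sim/config.yaml <<'YAML'
human_subjects: sim/human_subjects.tsv
mouse_subjects: sim/mouse_subjects.tsv
human_expression: sim/human_expression.tsv
mouse_expression: sim/mouse_expression.tsv
region_map: sim/region_map.tsv
n_resamples: 1000
YAML
neurocongruence all --config sim/config.yaml --outdir sim_out --seed 5
```

which fits both species' models, aligns the homologous regions, and writes
effect tables, variance tests, congruence correlations, transcriptional
similarity and null distributions, plus a machine-readable `summary.json`
(byte-identical across reruns with the same config and seed).

As a library:

```python
from neurocongruence import builtin_table1_fixture, percentage_bend_correlation
pairs = builtin_table1_fixture()
res = percentage_bend_correlation(pairs["human_beta"], pairs["mouse_beta"])
print(res.r, res.p)   # 0.2977 0.0209
```

## Layout

- `src/neurocongruence/homology_atlas.py` — homologous-region map, bundled
  effect-size table, compartment filtering
- `src/neurocongruence/volumetrics.py` — sex-effect models, FDR, Levene,
  harmonization, QC
- `src/neurocongruence/robust_stats.py` — percentage-bend and Pearson
  correlation, permutation p-values, Cook's distance
- `src/neurocongruence/congruence.py` — alignment, congruence correlation,
  similarity scores, quadrants
- `src/neurocongruence/expression.py` — region x gene matrices,
  transcriptional similarity, gene-subset nulls
- `src/neurocongruence/synthetic_data.py` — seeded generators and recovery
  reports
- `src/neurocongruence/pipeline.py`, `cli.py` — config-driven orchestration
  and the `neurocongruence` command

See `docs/methods.md` for the statistical details, simulator assumptions,
and known limitations.
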