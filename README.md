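# cytocross

Analysis toolkit for **bifurcated cytokine crosstalk** in transcriptomic
and ChIP-seq data, modeled on the two-cytokine stimulation design used
to study the hepatic acute phase response: cells are treated with IL-1β,
IL-6, or both (plus a non-treated control), and the question is which
genes the two cytokines induce **synergistically**, which they
**antagonize**, and which enhancer mechanism — *assisted loading* of
STAT3 by NF-κB — explains the synergy.

The package is aimed at computational biologists who want the full
analysis chain as tested, reusable functions rather than a collection of
one-off scripts: a negative-binomial differential test for gene and
ChIP fragment counts, the fold-change-based crosstalk classifier,
binding-site universe construction and assisted/unassisted site calls,
depth-scaled tag-density machinery (aggregation plots, per-site box-plot
densities, heatmaps), motif scanning and site–gene proximity analyses —
and a synthetic-data generator with a machine-readable truth table so
every classifier can be scored against planted ground truth.

## The statistics at the core

**Crosstalk classification.** With fold changes over non-treated (NT)
computed from condition-mean FPKM (offset 0.1), a gene is *induced* by a
treatment when FC ≥ 1.5 at BH-adjusted p ≤ 0.05. An IL-1β-induced gene
is *antagonized by IL-6* when FC_dual ≤ 1.2 (and symmetrically); a
dual-induced gene is *synergistic* when

    FC_dual ≥ 1.2 × FC_additive,   FC_additive = FC_IL1 + FC_IL6 − 1.

**Assisted sites.** Over the coordinated STAT3 binding-site universe
(peaks called under IL-6 and/or dual treatment), a site is *assisted*
when its dual-vs-IL-6 fragment-count contrast reaches FC ≥ 1.7 at raw
p ≤ 0.01 under the package's NB Wald test (per-site method-of-moments
dispersion, t-referenced; calibration verified by simulation).
H3K27ac enhancer calls use FC ≥ 2 at adjusted p ≤ 0.1.

**Tag density.** Each 50-mer read is extended to 150 bp in its 3′
direction; per-bp fragment coverage is scaled by 10⁷ / (non-mitochondrial
reads). Aggregation profiles use 10-bp bins over ±500 bp around site
centers; per-site densities are means over ±100 bp; heatmaps span ±4 kb
sorted high-to-low in a chosen condition.

## Worked example

Run the whole pipeline on the bundled reference synthetic preset (1,000
genes, 500 STAT3 sites of which 100 are planted assisted at a 4-fold
dual/IL-6 ratio):

```bash
cytocross run-all --seed 3 --outdir out
```

Excerpt of the summary it prints (seed 3):

```json
{
  "label_counts": {"unchanged": 780, "synergistic": 49, "antagonized_by_il6": 42,
                   "antagonized_by_il1": 43, "additive_dual": 43,
                   "il1_only": 17, "il6_only": 26},
  "sites": {"n_assisted": 99, "n_unassisted": 351, "percent_assisted": 22},
  "priming": {"assisted_nt_vs_il1_p": 9.36e-111, "unassisted_nt_vs_il1_p": 0.73},
  "lost_binding": {"n_lost": 83, "n_total": 100, "percent": 83},
  "assisted_nearest": {"synergistic": 35, "additive_control": 5}
}
```

Reading this: the classifier recovers the planted crosstalk classes
(50 planted per scored class); 99 of the 100 planted assisted sites are
called, making up 22% of the coordinated universe; H3K27ac density at
assisted sites rises sharply from NT to IL-1β (enhancer priming) while
unassisted sites show no significant change; under dominant-negative
NF-κB, 83% of assisted sites drop to statistical background (the
planted ablation was 90%, and the empirical-quantile rule recovers most
of it); and the gene nearest an assisted site is seven times more often
a synergistic gene than a fold-change-matched additive control.

Library-level usage mirrors the pipeline stages:

```python
from cytocross import synthetic, expression, sites

ds = synthetic.make_dataset(seed=3)
records = expression.build_crosstalk_records(ds.counts)   # per-gene labels
union = sites.merge_peak_union({c: ds.peaks[("STAT3", c)] for c in synthetic.CONDITIONS})
```

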