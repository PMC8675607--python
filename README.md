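# coexkey

Two-state weighted gene co-expression network analysis for time-course
RNA-seq, built to find **stress key genes**: genes that are unimportant in
the co-expression network of unstressed samples but become network hubs (or
otherwise central) under stress. The design it targets is a salt-stress
study in rice — two conditions (control, salt) × six sampling times
(0, 3, 6, 12, 24, 48 h) × three replicates = 36 libraries — but every stage
works on any two-condition time-course count matrix.

## What the pipeline does

1. **Preprocess** — drop genes with zero counts in more than 80% of
   libraries; compute median-of-ratios size factors
   (`f_s = median_g counts[g,s] / geomean_g`); screen for condition-responsive
   genes with a per-gene negative binomial Wald test (condition effect with
   log size-factor offsets, method-of-moments dispersion, `p < 0.05`).
2. **Networks** — Pearson correlation of `log2(normalized + 1)` over the
   screened genes; unsigned power adjacency `a_ij = |r_ij|^β` with β chosen
   as the smallest power whose degree histogram reaches scale-free fit
   R² ≥ 0.90 (fallback β = 6); the simple graph keeps pairs with
   `a_ij ≥ 0.1` (inclusive). Three networks are built: *global* (all 36
   samples), *normal* (control samples) and *salinity* (salt samples).
3. **Modules** — topological overlap matrix
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` on the
   global network; average-linkage clustering of `1 − TOM`, static cut,
   minimum module size 30, eigengene merging, and kME adoption of left-over
   genes. Module eigengenes (first PC of the z-scored member expression) are
   correlated with salt-time indicator traits; modules with `|r| > 0.50`
   and `p < 0.05` are significant.
4. **Centralities** — degree, betweenness (normalized by `(N−1)(N−2)/2` per
   component), closeness (1 / mean distance to reachable nodes) and
   clustering coefficient (`2e_v / k_v(k_v−1)`) on the normal- and
   salinity-state graphs, with descending percentile ranks.
5. **Key genes** — within each significant module and per measure, flag
   genes in the salinity top decile whose normal-state percentile is at or
   below the median; genes flagged by several measures carry a
   multi-measure flag.
6. **Enrichment** — one-sided Fisher (hypergeometric) over-representation of
   annotation terms in module or key-gene sets against the post-filter
   background, Benjamini–Hochberg corrected (`q < 0.05`).

A synthetic-data module generates 36-library count datasets with planted
co-expression modules, condition- and time-dependent module activity,
stress-rewired key genes and a null background, together with a
machine-readable ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from coexkey import AnalysisConfig, SimulationConfig, generate_dataset, run_all

data, truth = generate_dataset(SimulationConfig(seed=1))
report = run_all(AnalysisConfig(seed=1), data, "out/", truth=truth)
print(report.n_de_genes, report.module_sizes, report.significant_modules)
print(report.recovery)
```

On this seed the screen keeps 686 of 8,000 genes; five modules are detected
(sizes 70/60/51/49/43 plus 413 grey genes) and all five are significantly
correlated with a salt time point. The three networks are global 275
nodes / 5,690 edges, normal 530 / 2,764 and salinity 536 / 3,974. Against
the planted truth the module assignment reaches adjusted Rand index 0.996
and the differential-expression screen recovers 97% of the planted
condition-responsive genes at a 5% false-positive rate. 51 key-gene
candidates are flagged, of which 16 are the planted rewired genes
(recall 0.64, precision 0.31 — see `docs/methods.md` for why the
betweenness/clustering flags carry an irreducible false-discovery floor at
this sample size).

The same run from the shell:

```bash
coexkey simulate --seed 1 --outdir sim/
coexkey run-all --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --truth sim/truth.json --seed 1 --outdir out/
```

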