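# polyeff

Transcriptional and translational regulation analysis for polysome-profiling
expression data, built around the early adipogenesis setting: 3T3-L1
pre-adipocytes sampled before (0 h) and six hours after hormonal induction,
with mRNA split into a polysomal (ribosome-bound) and a non-polysomal (free)
fraction on each array.

`polyeff` is for analysts who have log2 intensity matrices from such a
two-fraction × two-timepoint design and want the full downstream chain:
spike-in normalization, per-gene efficiency statistics, nine-group
regulation classification, 5′TOP motif scanning and group-wise
overrepresentation tests.

## The model

With `p0, p6, np0, np6` denoting per-gene log2 condition means of the
polysomal/non-polysomal fractions at 0 h/6 h:

- **Translation efficiency** `TL = (p6 − p0) − (np6 − np0)` — the difference
  of time-related log2 fold changes between fractions; `TL > 0` means
  translationally up-regulated.
- **Transcription efficiency** `TC = (p6 + np6)/2 − (p0 + np0)/2` — the
  change in total log2 abundance; `TC > 0` means transcriptionally
  up-regulated.

Both contrasts are tested gene-by-gene with an empirical-Bayes **moderated
t-statistic**: the pooled four-cell residual variance `s_g²` (d_g = N − 4 df)
is shrunk toward a prior `s0²` with `d0` prior df,

    s̃² = (d0·s0² + d_g·s_g²) / (d0 + d_g),   t = effect / √(s̃²·Σc_i²/r),

on `d0 + d_g` df, with `(d0, s0²)` estimated across genes by method of
moments on `log s_g²` (trigamma inversion). Raw p-values are
Benjamini–Hochberg adjusted; a gene is called up/down when `fdr < 0.05` and
`|log2 effect| > 1` (rule configurable). The cross of the TC and TL statuses
yields nine regulation groups; group-wise 5′TOP-motif occurrence and classic
gene-count GO-term overrepresentation are tested with Fisher's exact test.

A 5′TOP motif is scanned as a cap-adjacent `C`, ≥ 3 pyrimidines, then `G`,
anchored at position 1, with consecutive motifs chained.

## Worked example

The numbered scripts under `analysis/` run the whole study on seeded
synthetic data (5,000 genes, 3 replicates per condition, group composition
matching the published classification):

```
python analysis/01_simulate.py
python analysis/02_normalize_and_fit.py
python analysis/03_classify_groups.py
python analysis/04_scan_top_motifs.py
python analysis/05_enrichment.py
```

Step 02 prints the fitted variance prior, e.g.

```
variance prior: d0 = 5.93, s0^2 = 0.0729 log2^2
```

(the planted prior is d0 = 4, s0² = 0.05; residual technical variation after
normalization inflates the estimate slightly). Step 03 prints the nine group
sizes and their marginals plus

```
true-group recovery: 97.9%
```

— the fraction of genes whose estimated group matches the planted truth.
Step 05 prints the per-group Fisher tests; the TC:up/TL:up group, where TOP
motifs were planted at elevated probability, leads with an odds ratio ≈ 19
at p ≈ 1e-144, and the planted GO terms top the enrichment table.

The same pipeline is available as a CLI (`polyeff run-all --seed 1
--out-dir out`) and stage-by-stage (`simulate`, `normalize`, `analyze`,
`classify`, `scan-top`, `enrich-top`, `enrich-go`), or programmatically:

```python
import polyeff as pe

data, truth = pe.simulate_expression(pe.SimulationConfig(n_genes=2000, seed=1))
normalized, _ = pe.normalize_spikein(data)
records = pe.analyze(normalized)            # TC, TL, t, p, fdr per gene
groups = pe.classify(records)               # nine-group classification
print(pe.marginals(groups))
```

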