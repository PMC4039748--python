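# Methods

## Design and estimands

The data are log2 intensities from a balanced two-fraction
(polysomal / non-polysomal) × two-timepoint (0 h / 6 h) array design with
r ≥ 2 replicates per cell. For each gene the four cell means
`p0, p6, np0, np6` define two linear contrasts:

- translation efficiency `TL = (p6 − p0) − (np6 − np0)`, coefficients
  (+1, −1, −1, +1) on the cell means;
- transcription efficiency `TC = (p6 + np6)/2 − (p0 + np0)/2`, coefficients
  (±1/2).

These satisfy the reconstruction identity `p6 − p0 = TC + TL/2` and
`np6 − np0 = TC − TL/2` (asserted to 1e-12 in the tests). The residual
variance `s_g²` is pooled over the four cells with `d_g = N − 4` degrees of
freedom; polysomal and non-polysomal fractions share one gene-wise variance.
A per-fraction variance model would be defensible, but with the small
replicate numbers typical of such designs the pooled fit is more stable and
keeps the two contrasts on one common scale.

## Moderated test

The gene-wise variances are modeled as draws from a scaled
inverse-chi-square prior with hyperparameters `(d0, s0²)`. The posterior
variance `s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g)` replaces `s_g²` in the
t-statistic

    t = effect / sqrt(s̃² · Σc_i²/r),

which follows a Student t distribution on `d0 + d_g` df under the null
(standard normal when `d0 = ∞`). The contrast scale `Σc_i²/r` is `4/r` for
TL and `1/r` for TC in the balanced case; unbalanced designs use
`Σ_cells 1/n_cell` (and a quarter of it for TC). Two-sided p-values are
used because the classification needs both directions.

Hyperparameters are fitted by method of moments on
`e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`: the excess of `var(e_g)` over
`ψ′(d_g/2)` identifies `d0` through `ψ′(d0/2)`, inverted by bisection on the
strictly decreasing trigamma (tolerance 1e-10); then
`s0² = exp(mean(e_g) + ψ(d0/2) − log(d0/2))`. Non-positive excess variance
yields the degenerate prior `d0 = ∞`, `s0² = exp(mean(e_g))`. Zero-variance
genes are excluded from the fit (their posterior variance is still defined
through the prior). One test cross-checks the fit against an independent
R implementation of the same moment estimator (limma's `fitFDist`); the two
agree to four significant figures on a common fixture.

Benjamini–Hochberg adjustment is applied per contrast over all non-spike-in
genes. Significance is `fdr < 0.05` and `|log2 effect| > 1`, both strict.
The fold-change arm of the rule is configurable (`both`, `TC_only`,
`neither`) because published borderline cases suggest analyses in this
field sometimes apply it to the transcription contrast only; the default
applies it to both.

## Normalization

Between-array normalization is a per-sample additive shift in log2 space
anchored on spike-in control probes: each sample's spike-in median is moved
onto the median of the per-sample spike-in medians. The median (not mean)
resists a corrupted control probe; the median-of-medians target makes
re-normalization an exact fixed point. Shifts below 1e-12 are snapped to
zero so repeated normalization is bit-identical. Gene-wise contrasts (TC,
TL) are invariant under any global constant, so the choice of target level
is inconsequential for inference; it merely preserves the overall intensity
scale. All samples are normalized jointly.

## Nine-group classification

The cross of TC status × TL status (up / unchanged / down) defines nine
groups, numbered 1 = TC:up/TL:up through 9 = TC:unchanged/TL:unchanged in
the conventional order. Marginal counts (TC-up, TC-down, TL-up, TL-down,
"only transcriptional" = TC significant with TL unchanged, "only
translational" = the converse) are sums of group sizes. The net-effect
score `(TC + TL)` summarizes the combined transcriptional and translational
influence on a gene's protein output.

## TOP motif scanning

A 5′TOP motif is an anchored pattern at the 5′ terminus: `C`, then a maximal
run of ≥ 3 pyrimidines (C/T), then `G`. The minimum run of 3 is the smallest
motif observed in published scans of this design; there is no maximum.
After a hit the scan resumes at the next base, so consecutive motifs form a
contiguous chain; scanning stops at the first failure. Because `G`
terminates any pyrimidine run, the greedy maximal-run scan is provably
equivalent to iterating the regex `^C[CT]{3,}G`, which the tests exploit as
an oracle on 10,000 random sequences. Coordinates are 1-based inclusive.
Internal (non-anchored) chains can be requested with a flag but are off by
default. A gene is TOP-bearing if any of its UTRs has ≥ 1 hit.

## Overrepresentation tests

Both applications build 2×2 tables (in-group/out-group ×
with/without feature) and use Fisher's exact test (scipy's exact
hypergeometric implementation; the tests verify it against full enumeration
of all tables with the observed margins).

- **TOP motifs:** each of groups 1–8 versus the remaining ones; two-sided
  by default (the odds-ratio-≠-1 null), significance `p < 0.05`. Genes with
  no UTR available are excluded and counted in the log.
- **GO terms:** classic gene-count enrichment of each group against the
  reference gene list — the grouped (groups 1–8) genes carrying at least one
  annotation in the tested namespace (BP or MF). Annotations are propagated
  along `is_a` edges only (true-path rule); `part_of` is ignored, matching
  the classic gene-count variant. One-sided (greater) by default,
  significance `p ≤ 0.05`, no multiple-testing adjustment — raw-p
  thresholding is the convention for the classic variant and the output
  preserves it deliberately. Terms with zero annotated universe genes are
  skipped. The slight asymmetry between the two significance conventions
  (`<` vs `≤`) is preserved intentionally.

For gene-level GO counting, transcript-level records should be collapsed to
one gene symbol; classification itself stays at the transcript/probe level.

## Synthetic data

The generator draws, per gene: a group label (default composition =
relative sizes of the published nine-group classification), an effect
magnitude Uniform(1.25, 3.0) signed by the label (so detected effects
straddle the |log2FC| > 1 rule), a variance `σ_g² = s0²·d0/χ²(d0)` with
defaults `d0 = 4`, `s0² = 0.05 log2²`, and a baseline Uniform(6, 12).
Condition means follow the reconstruction identity exactly; replicates are
Normal(μ, σ_g²); each array receives one additive offset
Normal(0, array_offset_sd²), default 0.25 log2, applied to every probe
including the spike-ins so spike-in normalization can remove it. Spike-ins
(default 20) have exactly zero effects. Replicates default to r = 3, a
typical array-study depth. Group counts are apportioned by largest
remainder, so small nonzero proportions never error. UTRs plant
`C + 3–12 pyrimidines + G + 20–200 nt tail` in TOP-flagged genes (default
flag probability 0.5 in group 1, 0.05 elsewhere) and redraw unflagged
sequences until position 1 opens no motif. The toy ontology grows a rooted
DAG (each term, 1–2 parents among earlier terms), annotates genes at a
background rate of 0.05 and target-group genes at 0.25 for the planted
terms.

What the generator does **not** emulate: probe-level microarray artifacts
(dye bias, spatial effects, background), intensity-dependent variance,
correlated genes, multi-probe genes, or realistic GO topology. Passing
tests therefore demonstrate correctness of the statistical machinery under
the model's own assumptions, not robustness to real-array pathologies.

## Problem sizes and numerical choices

The test suite runs the simulation-based checks at 400–2,000 genes over 20
seeds (label recovery, null false-discovery rate) and 10,000 genes for
prior recovery; these sizes give stable averages while keeping the whole
suite around ten seconds. Fisher enumeration oracles use margins ≤ 30;
two-sided table inclusion uses the standard `(1 + 1e-7)` relative guard
against floating-point ties. Degenerate inputs: zero posterior variance
yields p = 0 with a warning; empty sequences yield empty hit lists; a
group with no motif-status genes reports p = 1 with a warning; an empty GO
universe is an error.

## Known limitations

- The moderated model assumes exchangeable gene variances from one
  inverse-chi-square prior; strong variance-mean trends would call for an
  intensity-dependent prior, which is not implemented.
- Spike-in normalization corrects additive (multiplicative-in-intensity)
  array effects only; no quantile or loess normalization is offered.
- The TOP scanner is anchored at position 1 by design; biologically
  relevant motifs a few bases downstream of an imperfectly annotated 5′ end
  are missed unless internal scanning is enabled.
- GO enrichment implements only the classic gene-count Fisher variant; no
  elim/weight decorrelation, and no semantic-similarity reduction of the
  resulting term lists.
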