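# Methods

This note documents the models, parameter choices and numerics behind
phosflow, and what the synthetic experiments do and do not establish.

## Pipeline model and assumptions

The pipeline models a multiplexed TMT phosphoproteomics run as a
peptide × channel matrix of positive reporter intensities

```
V[i, j] = baselineᵢ · channel_scaleⱼ · group_effectᵢⱼ · noise
```

with multiplicative log-normal measurement noise, per-channel loading
biases, and group effects (fold changes) confined to a subset of
regulated peptides. Quality problems enter as PSM-level covariates:
search-engine ion score, precursor isolation interference (the percent of
the isolation window's signal not from the target peptide — which both
disqualifies bad scans and down-weights retained ones), a raw-intensity
floor, and Percolator FDR.

### Filtering

Thresholds default to ion score > 15, interference < 30%, median TMT
signal > 1500, FDR < 1e-2; all comparisons strict, so boundary values
fail. Transgene-derived peptides are exempt from the FDR gate only.
Missing quality values fail their criterion. Removals are attributed to
the first failing gate in the order listed — the retained set is
order-independent, only the report attribution depends on it. Filtering
runs on raw intensities, before normalization, because the median-signal
floor is a raw-signal criterion.

### Constrained normalization

Alternating scaling: rows divided by their mean, columns by the mode of
a Gaussian KDE of the column (Scott bandwidth σ̂·n^(−1/5)). Iteration
stops when every row mean is within `tol` (default 1e-6) of 1 and every
column mode within `mode_tol` (default 1e-4), or at `max_iter` (200)
sweeps.

**Feasibility.** The two constraint families are not always jointly
satisfiable. After row-mean centering, the matrix is invariant to any
*uniform* rescaling of the columns, so the free column degrees of freedom
can only equalize the column modes at some common value m\* — the
mode/mean ratio of the cross-sectional noise distribution — not move
them to 1. For symmetric or degenerate noise m\* = 1 and the iteration
converges (separable baseline × bias matrices converge in one or two
sweeps, exactly); for skewed noise (log-normal with CV 0.1, m\* ≈ 0.985)
the iteration enters an exact two-state cycle. The implementation
detects the cycle (matrix change per sweep below `tol`), stops, and
returns the result with a non-convergence flag rather than an exception.
The *relative* channel corrections — all that fold-change ratios depend
on — converge in either case; only the overall level oscillates by m\*.

**KDE mode numerics.** The mode is located on a dense uniform grid over
[min, max] whose density is evaluated by binning the sample (4,096 bins
by default, i.e. bin width far below the bandwidth) and convolving with
the Gaussian kernel via FFT; the winning neighborhood is then re-scored
with one exact direct-sum evaluation on a 65-point local grid and
polished by parabolic interpolation of the peak triplet. The estimator is
deterministic and exactly scale-equivariant (`kde_mode(c·x) =
c·kde_mode(x)`), which is what makes a column divided by its mode land on
mode 1 to float precision. Agreement with a brute-force dense-grid
evaluation of `scipy.stats.gaussian_kde` is tested to ~1e-3 in data
units.

The per-channel scale estimate implied by mode centering is
variance-limited: on 50-peptide matrices at 10% CV, the recovered
relative channel scales deviate ~3–6% (maximum over 6 channels) from the
planted truth from sampling noise alone, shrinking to ~1% at 5,000
peptides with no systematic trend.

### Duplicate grouping

Grouping key is (sequence, full localized phosphosite assignment): scans
that differ in site localization are *not* combined, matching
peptide-level reporting granularity. Weighted mean with wᵢ = 1 −
interferenceᵢ/100; groups whose weights sum to zero are dropped with a
warning. The grouped value always lies within the per-channel range of
its members and is invariant to input order.

### Replicate runs

When the same tissue is run on multiple plexes, per-run peptide fold
changes are merged by `merge_run_fold_changes`: combination on the log
scale, median by default (mean optional). This is an interpretation —
merging before vs after normalization and the choice of median are not
dictated by the pipeline's inputs — and is therefore an explicit policy
option rather than a fixed step.

### Differential statistics

FC is the ratio of normalized group means (an alternative — mean of
per-animal ratios — is deliberately not the default; with balanced
channels the two differ only at second order). The test is the classical
pooled-variance Student's t (two-sided) with a Welch switch. Zero
variance in both groups returns p = 1 at equal means (t = 0 in both
variants). Rows are complete-case within the contrast; rows left with
fewer than two finite values per group, or a non-positive group mean, are
flagged invalid and excluded from classification. Labels use strict
thresholds (up: FC > 1.25, p < 1e-2; down: FC < 0.8, p < 1e-2). **No
multiple-testing correction** is applied to peptide p-values; downstream
set statistics are permutation-calibrated instead.

## Motif enrichment

Windows are 15-mers centered on sites with localization probability
strictly greater than 0.75; each site of a multiply-phosphorylated
peptide gets its own window. Flanks extend into the protein sequence
when one is supplied and contains the peptide; otherwise 'A' pads the
termini (the padding residue therefore inflates alanine counts
symmetrically in foreground and background — a deliberate, simple
convention). Identical windows are collapsed with median-combined
quantification values; enrichment itself uses *counts* of the collapsed
windows, not quantification weights.

The log-odds statistic −log10(sf(k−1)/cdf(k)) is computed in log space
from the exact hypergeometric log-PMF (cached log-factorials +
log-sum-exp), so extreme cells never underflow and no pseudocounts are
needed. The reported sign is the enrichment direction sign(k/n − K/N);
the magnitude is |−log10(sf/cdf)|. Forced cells (K = N) and a foreground
equal to its background give exactly 0. The foreground selection for
motif analysis is p < 0.05 with FC > 1.25 or FC < 0.8 — deliberately
looser in p than the regulation clusters — and the default background is
every localized window in the experiment, of which the foreground must
be a subset.

Pattern matching aligns the pattern's phospho-center class (lowercase,
e.g. `[st]`) to the window center and counts matches at non-wildcard,
non-center positions only; multi-site peptides report the maximum over
their windows.

## Cell-type enrichment

Candidate types are the displayed atlas categories minus the progenitor
exclusions (OPC, newly formed oligodendrocytes), which appear in neither
numerators nor denominators; the displayed oligodendrocyte category is
the myelinating columns only. The ratio criterion μ_t/Σμ_other > 2.5 is
strict; a gene expressed in exactly one candidate type qualifies
(infinite ratio), an all-zero gene never does. Should a gene qualify for
several types (possible only through exclusions), the largest ratio wins
and exact ties are left unassigned. For cluster scoring, genes without
an assignment are dropped from both cluster and background totals (the
alternative — counting them in n and N — shrinks all LOEs toward zero;
dropping matches the "genes enriched in any cell type" universe).
Multi-protein peptides are excluded before gene mapping; the background
is genes with at least one quantified PSM.

## PSEA

Site scores are z-scored **log** fold changes (medians over redundant
peptides); z-scoring on the log scale makes up- and down-regulation
symmetric around 0. Ranking ties break lexicographically on the site
identifier, making the whole analysis deterministic.

Running sum: hits add |score|^w (w = 0.75) normalized by the summed hit
weights, misses subtract 1/(L − overlap); ES is the extremum of largest
magnitude (positive chosen on an exact ± tie). At w = 0 this reduces to
the classical unweighted KS-style statistic; |ES| ≤ 1 always, and
negating all scores negates ES up to tie ambiguity. All-zero hit scores
fall back to uniform hit weights.

The null scrambles the score-to-identifier assignment: one shared
permutation of rank positions per iteration, applied to every set
(preserving inter-set overlap structure). A second mode
(`psea_row_null`) scrambles which peptide row carries which fold change
and re-collapses/re-ranks per iteration, propagating redundancy
structure into the null at ~L× the cost. Null ES for a set is computed
only at its candidate extrema (just before/after each hit), an O(overlap)
identity with the full running sum that the tests verify directly.

Per set: NES = ES / mean|same-sign null ES|; the empirical p is
+1-corrected **within the same-sign stratum**, p = (1 + #{same-sign
nulls ≥ |ES|}) / (#same-sign nulls + 1). Normalizing the numerator and
denominator over the same stratum keeps the null p distribution
near-uniform (a same-sign count over an all-permutation denominator
would be ~2× anti-conservative); the +1 correction bounds p ≥
1/(nperm+1). q-values follow the sign-stratified empirical FDR over
pooled normalized null scores, clipped to [0, 1]. Sets overlapping the
ranking by fewer than 20 sites (default) are excluded with a recorded
reason.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes —
log-uniform baselines over [1e3, 1e7] (so the median-signal floor is
actually exercised), channel scales drawn from [0.5, 2], log-normal
noise at 10% CV, 5% spiked up (2×) and down (0.5×) peptides, 20%
duplicate PSMs, interference drawn from a near-zero body with a tail
above 30%, and ~5% planted failures per quality gate. Motif, kinase and
atlas generators plant single known effects (a 4× residue boost at one
position, a +1.5σ score shift on a 40-site set, marker genes exceeding
the ratio criterion by construction) and record every planted truth in a
ledger; recovery tests compare against the ledger, never against
re-derived outputs. Identical configurations (including seed) reproduce
byte-identical tables.

What passing these tests does **not** show: the generator draws
independent peptides with a shared noise level — real data carry
correlated peptides (shared proteins), intensity-dependent variance,
missing channels, batch structure across plexes, and search-engine score
distributions far from uniform. Planted-truth recovery demonstrates the
computations are correct, not that the thresholds are optimal for any
particular instrument.

## Problem sizes and runtime

Default desk-scale sizes: 500 peptides × 10 channels for the pipeline
simulation; 500/5,500 foreground/background motif windows; 500 sites,
51 sets, 1,000 permutations for PSEA; 50 sets × 20 repeats for null
calibration. The full test suite runs in ~30 s and the acceptance script
in ~10 s on one CPU.

## Known limitations

- No cross-plex bridging/IRS normalization; replicate runs are merged at
  the fold-change level by the documented policy.
- The mode/mean inconsistency means absolute normalized levels carry the
  residual factor m\* for skewed noise; only ratios are interpretation-
  safe (which is how the pipeline uses them).
- Manually validated or re-assigned spectra (site re-assignment by visual
  inspection) have no reproducible rule and are out of scope.
- pLogo-style fixed-position significance thresholds (Bonferroni red
  lines) and motif-x-style iterative extraction are not implemented; the
  logo reports signed LOE per cell.
- Peptide p-values are raw by design; interpret single-peptide calls
  accordingly.
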