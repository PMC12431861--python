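# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the published descriptions of
these estimators leave the details open, and what the synthetic-data
generator does and does not emulate.

## Coordinate and format conventions

All genomic arithmetic is 0-based, half-open (BED convention); a single
conversion layer (`core.to_one_based` / `from_one_based`) handles 1-based
dialects. Contact maps are interchanged as sparse triplet text
(`bin_i TAB bin_j TAB value`) with a BED-like sidecar bin table; the
reader mirrors either triangle and sums duplicate records, and writers
emit deterministic line order so outputs are checksummable. narrowPeak
summit offsets are honoured when present; a peak without a summit column
gets its interval midpoint (the peak caller that produces summits is
outside this package's scope). JASPAR PFM counts are converted to
probabilities with pseudocount 0.01. A `.cool` reader is not provided;
the triplet-text dialect covers the same contract and is inspectable in
tests.

Bins with zero marginal in the raw matrix are treated as unmappable and
masked from every downstream statistic. This is a convention: real
pipelines use an explicit mappability mask, which can be supplied via
`ContactMatrix(valid_mask=...)`.

## Synthetic contact maps

The generator composes, per bin pair `(i, j)`:

```
e_ij = A · (|i−j|+1)^(−α)
       · Π_boundaries [γ if the boundary lies strictly between i and j]
       · Π_loops [1 + (λ−1)·(G_ij + G_ji)],  G = isotropic Gaussian at (b_i, b_j)
       · (1 if same compartment label else ρ)
       · b_i · b_j
```

scaled so the upper triangle sums to the target depth, with counts drawn
`Poisson(e_ij)` for `i ≤ j` and mirrored. Defaults: `α = 1` (the
canonical intra-chromosomal decay slope), resolution 10 kb (the working
resolution of the loop and insulation statistics), boundary attenuation
`γ = 0.2` (a strong TAD boundary), loop amplitude `λ = 4` with spread
`σ = 1` bin (a focal 5×5-scale enrichment), compartment affinity
`ρ = 0.5`, and depth 10⁶–2×10⁶ counts per simulated chromosome — deep
enough that per-pixel counts at loop distances are in the tens, the
regime the estimators assume.

What the generator does **not** emulate: read-level artefacts
(duplicates, ligation junctions), overdispersion beyond Poisson,
fragment-level resolution effects, trans contacts, and correlated
biological replicates (replicates are independent Poisson draws from the
same expectation). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not
robustness to every artefact of real libraries.

The phasing track encodes compartment labels as ±1 plus optional
Gaussian noise, giving a tunable correlation (`r = 1/√(1+σ²)`), mimicking
GC% or gene density. The peak/genome generator plants PWM-sampled motifs
at peak summits on random strands and assigns replicate signals as
lognormal noise times a per-class condition fold change
(gain ×2, loss ×0.5, stable ×1 by default; σ_log = 0.1).

## IPF balancing

Symmetric Sinkhorn updates (`w ← w·√(target/marginal)`) rather than
alternating row/column fits, so the matrix stays symmetric at every
iteration. The target marginal is the mean valid marginal of the input,
which preserves the count scale — important because cross-sample loop
comparisons use normalized values directly and assume libraries of
similar depth. Convergence is declared when the coefficient of variation
of valid-bin marginals falls below `tol` (default 1e-5, max 200
iterations; non-convergence is flagged, not fatal). Balancing an
already-balanced matrix is a no-op up to `tol`, and planted multiplicative
biases are removed to machine precision (the acceptance report measures
the residual spread).

## Loop scores

Loop signal = mean, loop strength = sum, of the 5×5 window at the loop
centroid; masked cells contribute zero to the sum and are excluded from
the mean's denominator. The donut background is the mean of the
per-square means of up to 15 5×5 squares drawn uniformly *without
replacement* from the ring of centres at Chebyshev distance 8 from the
centroid, after removing squares that leave the matrix or contain any
on-or-below-diagonal cell. The three published donut numbers (19×19
donut, 9×9 exclusion, squares "at a distance of 8 pixels") are mutually
inconsistent for 5×5 squares — a square centred 8 bins away reaches 10
bins out — so the explicit distance 8 is honoured and the 1-bin overhang
beyond the nominal 19×19 accepted; the ring radius is configurable.
`LS = log2((signal+ε)/(background+ε))` with `ε = 1e-9` guarding empty
backgrounds. Per-loop RNG streams derive from `(seed, loop index)` so
scores are independent of loop-list order; unscoreable loops (window out
of bounds, fully masked, no donut candidates) are flagged, never
silently dropped.

Near the diagonal the decay curve is convex, so the ring average exceeds
the centre expectation and featureless maps score slightly negative LS
(≈ −0.17 median at 12–40-bin separations, ≈ −0.05 at 20–100 bins). The
null-calibration checks therefore probe loops at 20–100-bin separations
(200 kb–1 Mb), the scale of architectural loops — consistent with the
>100-kb filter used for aggregate analyses.

APA averages the 21×21 windows (halfwidth 10) at the centroids of loops
spanning strictly more than 100 kb; the APA score is the centre pixel
over the mean of the lower-left (short-distance) 6×6 corner.

Condition-specific calls use strict inequalities in all wild-type ×
mutant pairs on both strength and LS ("consistently higher" read
strictly; ties break consistency). Note the statistical character of
this rule: with two samples per condition, a loop whose expectation is
*unchanged* still satisfies all-pairs strength consistency with
probability 1/3 by pure order statistics, so the rule's specificity on
stable loops is bounded by chance (measured ~10–35% across seeds when
combined with LS) and does not improve with sequencing depth. The rule
is reproduced as published; users needing controlled error rates should
treat these calls as a screen, not a test.

## Insulation

`IS(i) = log2(((U+D)/2 + ε)/(X + ε))` on the expected-normalized matrix,
with 3×3 squares and half-offset `d = 5`, putting the cross square's
centre 10 bins off the diagonal. The published description fixes only
the square geometry ("three squares of 3×3 pixels, 10 bins from the
diagonal"); the log-ratio form and the expected-normalization are this
package's reconstruction, chosen so a featureless matrix scores ≈ 0 and
the 0.75 peak threshold is meaningful. Both are configurable
(`expected_normalize_first`, and `d = 10` for the alternative reading of
the phrase). IS is undefined within `d + 1` bins of the matrix edge and
wherever a square has no valid cell; missing bins break peak runs. Peaks
are maximal runs of ≥ 3 bins with `IS > 0.75` (strict); the reported
summit is the leftmost maximal bin. Differential insulation averages
`IS_ref − IS_alt` over each peak's co-defined bins.

On a sharp planted boundary the IS is constant on the plateau of bins
whose cross square straddles the boundary (width ≈ 2d − s + 1); the
plateau is centred on the boundary, and recovery is scored as any peak
bin within ±2 bins of the planted position.

## Compartments

Observed/expected (per-distance mean over valid pairs) → Pearson
correlation matrix over valid bins → eigendecomposition, keeping the
three leading eigenvectors → selection by maximal |Pearson r| against
the phasing track → orientation so the correlation is positive (positive
values = A). PCA on the correlation matrix of the O/E map is one of two
published orders of operations (the other applies PCA to the normalized
map directly); the implemented order is stated here and exercised by the
recovery tests. The saddle assigns valid bins to `n_q` equal-occupancy
eigenvector quantiles (default 50; 10 in the compact acceptance run,
where 300-bin chromosomes would leave too few bins per quantile at 50)
and averages O/E per quantile pair; rows/columns run lowest (B) to
highest (A). This stage consumes IPF-balanced matrices rather than the
Knight–Ruiz weights some pipelines use; on synthetic checkerboards the
eigenvector sign structure is insensitive to that choice.

## Peaks and motifs

PWM hits score `Σ log(p_base/background)` with min–max relative
normalization, matching the "minimum 80% of the best score" hit
convention; N bases score as background. Reverse-strand hits are
reported at their forward-coordinate window start. The best summit motif
scans the 50-bp window centred on the summit (clipped at chromosome
ends); ties break to the highest raw score, then leftmost, then the +
strand. Differential occupancy follows the replicate-congruent rule:
gain iff `alt ≥ 1.25·ref` and loss iff `alt ≤ 0.75·ref` in *every*
replicate pair ("altered by at least 25%" read as a symmetric change
fraction, not a symmetric ratio; threshold configurable); a zero
reference with positive signal counts as gain. The count-based
statistical testing some differential analyses add on top of this rule
is out of scope here.

Promoters are TSS ± 500 bp for enhancer definition and TSS ± 3 kb for
peak annotation (two windows used for two different purposes, both
retained). Enhancers are open-chromatin peaks overlapping an acetylation
peak by ≥ 1 bp and no promoter. The smallest containing loop domain
minimizes the anchor-midpoint span, ties to the leftmost 5′ anchor;
flank counts sum enhancers overlapping the two 500-kb windows outside
the domain body, counting an enhancer once per flank it touches.

## Pipeline

`run_pipeline` executes simulate → balance → loopscore / insulation /
compartments from a YAML-serializable config, records SHA-256 checksums
of all inputs and outputs in a JSON manifest (no timestamps, so re-runs
are checksum-identical), derives all randomness from the single global
seed, and on failure persists completed-stage outputs plus an error
record naming the stage and missing artifact.

## Problem sizes

The default test and acceptance runs use single synthetic chromosomes of
300–900 bins (3–9 Mb at 10 kb) at depths of 2×10⁵–2×10⁶ counts, 8
planted boundaries, 80 loops (40 differential + 40 stable) and 200 peaks
— sizes chosen so every recovery statistic is estimated from dozens of
planted instances while the full suite completes in well under a minute
per module.

## Known limitations

* The IS formula and the PCA order of operations are reconstructions of
  under-specified published procedures (flagged above, both configurable).
* Poisson noise only; real Hi-C replicates are overdispersed, so
  real-data error rates will exceed the synthetic ones.
* The condition-specific loop rule has chance-level specificity at 2×2
  samples (see above).
* Inter-chromosomal (trans) contacts, multi-resolution loop merging and
  de novo loop calling are out of scope; loop lists are inputs.
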