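# loopscape

Quantification of 3D-genome architecture from Hi-C and ChIP-seq style
data: matrix balancing, chromatin-loop scoring, TAD-boundary insulation,
A/B compartment saddles, CTCF motif orientation and enhancer-neighbourhood
statistics — together with a synthetic-data generator that plants every
one of those structures with known ground truth, so the whole pipeline is
testable without any sequencing data.

## Who this is for

Chromosome-conformation studies routinely ask whether loops, insulators
and compartments *strengthen or weaken* between two conditions — for
example between pluripotent and lineage-committed cells, or between
wild-type cells and cells lacking an RNA-binding protein that partners
with the architectural factor CTCF. `loopscape` implements the
quantification layer of such a study as a reusable, tested library: it
consumes binned intra-chromosomal contact matrices (sparse triplet text
with a bin table), loop lists (BEDPE), peaks (BED/narrowPeak), coverage
(bedGraph), genome sequence (FASTA) and motifs (JASPAR PFM), and produces
loop scores, differential-loop calls, insulation tracks and peaks,
compartment eigenvectors and saddles, oriented motif annotations and
differential peak-occupancy calls.

## The statistics at the core

* **IPF balancing.** Raw contact counts carry multiplicative per-bin
  biases `b_i`. Iterative proportional fit finds weights `w_i` such that
  `K_ij = M_ij · w_i · w_j` has equal row sums over valid bins
  (symmetric Sinkhorn updates `w ← w·√(target/marginal)`).
* **Loop score (LS).** For a loop with centroid pixel `(i, j)`, the loop
  signal is the mean of the 5×5 balanced-matrix window at the centroid and
  the loop strength its sum. The local background is the mean of 15
  randomly drawn 5×5 squares whose centres lie on the Chebyshev ring of
  radius 8 around the centroid (the annulus of a 19×19 donut with a 9×9
  core removed), never crossing the diagonal.
  `LS = log2(signal / background)`; loops with `LS > 1` whose anchors
  carry convergently oriented CTCF motifs (forward on the 5′ anchor,
  reverse on the 3′) are classified *architectural*.
* **Condition-specific loops.** A loop is called weakened (or
  strengthened) only when, in *every* wild-type × mutant sample pair, both
  its strength and its LS are strictly higher in the same condition.
* **Insulation score (IS).** Per bin, three 3×3 squares of the
  expected-normalized map: two intra-domain squares at `(i±d, i±d)` and a
  cross square at `(i−d, i+d)` (10 bins off-diagonal at `d = 5`);
  `IS = log2(((U+D)/2)/X)`. Insulation peaks are runs of ≥ 3 consecutive
  bins with `IS > 0.75`; differential insulation is the per-peak mean of
  `IS_ref − IS_alt`.
* **Compartments.** First three eigenvectors of the Pearson correlation
  of the observed/expected map; the one best correlated with a phasing
  track (GC%-like) is chosen and oriented, and a saddle matrix averages
  observed/expected between eigenvector quantiles (upper-left = B–B).
* **Peaks and motifs.** Log-odds PWM scanning with min–max relative
  scores (hit = ≥ 80% of the best attainable score), best motif in the
  50-bp summit window, AUC/mean summit signals, and the
  replicate-congruent ≥ 25% change rule for differential occupancy.
* **Regulatory neighbourhoods.** Enhancers = open-chromatin peaks
  overlapping acetylation peaks outside ±500-bp promoters; each gene's
  smallest containing loop domain is found and enhancers are counted in
  the 500-kb flanks of its two anchors.

## Worked example

```python
from loopscape.synthgen import SimParams, LoopSpec, BoundarySpec, simulate_contact_map
from loopscape.balance import ipf_balance
from loopscape.loopscore import score_loops
from loopscape.insulation import insulation_track, insulation_peaks

params = SimParams(
    n_bins=300, depth=1_000_000,
    loops=[LoopSpec(bin_i=100, bin_j=130, amplitude=4.0, spread=1.5)],
    boundaries=[BoundarySpec(bin=200, attenuation=0.2)],
    seed=1,
)
matrix, truth = simulate_contact_map(params)
balanced = ipf_balance(matrix)
print(f"IPF converged in {balanced.n_iterations} iterations")

(quant,) = score_loops(balanced, truth.loops, seed=7)
print(f"loop signal {quant.signal_mean:.2f}, background {quant.background:.2f}, "
      f"LS = {quant.ls:.2f}")

track = insulation_track(balanced)
for peak in insulation_peaks(track, threshold=0.75, min_run=3):
    print(f"insulation peak: bins {peak.start_bin}-{peak.end_bin}, "
          f"mean IS = {peak.mean_is:.2f}")
```

prints

```
IPF converged in 12 iterations
loop signal 43.68, background 24.17, LS = 0.85
insulation peak: bins 196-204, mean IS = 2.00
```

The planted loop (4-fold focal enrichment at bins 100/130) scores well
above the genome-wide null (LS ≈ 0 on featureless maps), and the planted
boundary at bin 200 is recovered as an insulation peak centred on it.
The same stages are available from the shell via the `loopscape`
executable (`simulate`, `balance`, `decay`, `apa`, `loopscore`,
`diffloops`, `insulation`, `diffinsulation`, `compartments`,
`annotate-motifs`, `diffpeaks`, `enhancers`, `flankcount`, `run`).

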