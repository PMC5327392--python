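# Methods

## Model and assumptions

The package quantifies co-association between a ChIPed transcription
factor and a candidate partner motif through the spatial distribution of
the partner's predicted binding strength around ChIP-seq peak points. The
underlying assumption is purely positional: if the two factors bind
cooperatively, strong matches to the partner's motif are over-represented
close to the peaks and their density decays with distance; a motif with no
relationship to the ChIPed factor matches the sequence equally well at
every distance. The statistic makes no use of motif occurrence counts
against a genomic background, so no background peak set or GC-matched
control regions are required — composition effects are handled inside the
score (see *Second-order differences*).

### Binding scores

Motifs are position frequency matrices Θ (4 × l, columns summing to 1),
read from TRANSFAC flat files. Count blocks and frequency blocks are both
accepted; a column sum above 1.5 flags counts, and in either case cells
are divided by their column sum, which also absorbs rounding drift in
frequency blocks. Before scanning, every matrix is regularized with a
pseudocount ε: Θ′ = (Θ + ε)/(1 + 4ε). The default ε = 0.001 bounds the
log-odds scores without perturbing column ranks or, in practice, motif
rankings.

A placement *s* scores `Σ_i log(Θ′[s_i, i]/0.25)` (natural log; the base
cancels in the normalization). Because the analytic maximum and minimum of
this sum are the per-column maxima and minima of Θ′, each score maps
linearly onto V ∈ [0, 1]. Scanning is strand-agnostic by default: each
start is scored with Θ′ and its reverse complement and the larger V kept
(the two orientations share the same min/max, so their V values are
directly comparable). Placements overlapping an ambiguous base (N) are
deterministically assigned V = 0; a degenerate motif whose max and min
coincide (the uniform matrix) maps every placement to V = 0.5.

### Windows and distance bins

Peak inputs are peak *points*; a 3-column BED interval is reduced to its
midpoint. Around each 1-based peak coordinate p the half-open span
[p − m, p + m) — 2m bases with the peak base at window offset m — is
extracted; peaks whose window would cross a contig edge are skipped, not
truncated, because a partial window would distort the bin occupancies.
The default m = 1000 bp matches the package's reference examples.

Each placement is assigned to one of b bins (default b = 40, bin width
m/b = 25 bp) by the unsigned distance of its *center* from the peak;
the two sides of the peak fold into the same bin. The fold uses
complementary half-open conventions (right side [j·w, (j+1)·w), left side
(j·w, (j+1)·w]), so for any motif length each bin receives exactly
2m/b placements per window, provided placements may straddle the window
edge. For that reason the pipeline extracts each window with a symmetric
flank equal to the longest motif: exactly 2m placements per window have
their centers inside the ±m span, every bin has identical occupancy
r = 2mn/b, and the descending-order matrix needs no padding. This
equal-occupancy construction is not cosmetic: if the outermost bin is
systematically short (as happens when only fully-contained placements are
scored) and is padded with zeros, every motif — signal or decoy — picks up
the same spurious positive S₁/S₂ offset, and the null calibration below
would fail. When windows are supplied without flanks the builder still
works, padding short columns with V = 0 at the bottom, but the flanked
path is the default and the calibrated one.

### First-order differences and S₁

Within each bin the V scores are sorted in descending order, forming the
r × b matrix Mₛ. The first-order adjacency difference
f₁[i, j] = Mₛ[i, j] − Mₛ[i, j+1] measures, rank by rank, how much stronger
binding is in bin j than in bin j+1. Region sums of f₁ over the top t
rows are weighted by a gamma density evaluated at region midpoints,
g(j + ½ | c, γ), and summed into S₁. Defaults: c = 1, γ = b/4 bins — an
exponential decay over distance, so score drops near the peak dominate.
These were chosen once for monotonicity; the shape of the decay barely
matters compared to the choice of t (next paragraph).

**Truncation depth t.** t is the number of top rows of the sorted columns
that contribute. It is the parameter that gives the statistic its power:
the top order statistics of a bin are tight (standard error of a top-5 %
sum is small), while full-column sums fluctuate with the sequence noise of
the whole bin. Writing the full-depth statistic as
S₁ = Σⱼ (gⱼ − gⱼ₋₁)·(column sum)ⱼ plus boundary terms shows the problem:
the g₀·(bin-0 sum) boundary term has a null standard deviation growing
like √(n·r), which at realistic sizes swamps any planted signal. The
default is therefore the single fixed depth t = 5 % of r. A grid of
depths with t\* = argmax S₁(t) is fully supported (`t_grid`), but an
argmax over several depths makes E[S] > 0 for *every* motif — the maximum
of mean-zero correlated variables — biasing the null; with a single fixed
depth, exchangeability of the distance bins under the null makes
E[S₁] = 0 exactly. Users reproducing an adaptive-t analysis can pass
`t_grid=(0.01, 0.05, 0.1, 0.25, 0.5, 1.0)` and accept the offset, which
cancels in comparisons *between* motifs scored on the same dataset.

### Second-order differences and S₂

Base-composition gradients (CG/AT bias around peaks) shift the *level* of
V in a bin without reflecting true binding enrichment. The second-order
difference divides each f₁ column by its own largest absolute entry,
Dⱼ = maxᵢ|f₁[i, j]|, giving f₂ ∈ [−1, 1] (an all-zero column stays zero).
Each region then contributes σ(zⱼ) − ½ to S₂, where zⱼ is the *mean* of
the f₂ column and σ the logistic sigmoid; a null region contributes
exactly 0 and extreme trends saturate at ±½. The mean (rather than the
raw column sum) is the deliberate choice here: with tens of thousands of
rows a raw sum drives the sigmoid to ±½ for every region on noise alone,
turning S₂ into a ±½ coin flip per region whose variance would drown S₁
in the combined score. With the mean, S₂ is a bounded, smooth trend
summary that is zero in expectation under the null (swapping two adjacent
bins negates zⱼ and leaves Dⱼ unchanged).

### Combined score and evaluation

S = ω₁·S₁ + ω₂·S₂ with defaults ω₁ = ω₂ = 0.5; both weights are exposed.
Motifs are ranked by S (ties broken lexicographically by id). Evaluation
against a positive/negative labelling uses the ROC AUC with ties counted
½ (Mann–Whitney form; scikit-learn's implementation, cross-checked in the
tests against a brute-force concordant-pair count). Family-level
evaluation represents each motif family by its best-ranked member.

## Synthetic data

The generator emulates the positional premise at desk scale: an i.i.d.
background contig with P(G) = P(C) = gc/2 (default gc = 0.41,
mammalian-like), peak points spaced ≥ 2m + 200 bp so windows never
overlap, and one planted motif whose instances are sampled column-wise
from its PWM (so planted-site scores vary realistically rather than all
being the consensus) and written with probability `plant_prob` per peak at
an unsigned center distance d ~ Exponential(λ), side and strand uniform.
Defaults — 500 peaks, m = 1000, λ = 50 bp, plant_prob = 0.8, one planted
10-mer versus 20 decoy 10-mers, all motif columns Dirichlet(0.5) — are the
package's reference recovery conditions. The exponential law is one
convenient "peak-like" decay; the method only assumes monotone decay, not
its exact form.

What the generator does *not* emulate: nucleosome or mappability
structure, composition gradients around peaks (the background is
stationary), motif co-occurrence within families, overlapping peaks, or
read-level noise in peak calling. Passing recovery tests on this
generator therefore demonstrates the statistic's positional sensitivity
and calibration, not robustness to every artefact of real ChIP-seq data —
in particular the CG/AT mitigation of S₂ is exercised only lightly, since
the synthetic background has no composition trend.

## Numerical choices and degenerate inputs

* Natural log throughout; min–max normalization cancels the base.
* Degenerate uniform matrices (max − min < 1e-12) score V = 0.5.
* f₂ columns with Dⱼ = 0 are zero (guard against 0/0).
* t fractions are converted to depths with ceiling and deduplicated;
  argmax ties resolve toward the smallest depth.
* Bins that would receive no placements (windows shorter than the bin
  geometry allows) raise an error rather than silently producing empty
  columns.
* Peak coordinates are 1-based; window start/end are reported as the
  half-open [p − m, p + m) in those labels, which is the convention that
  makes a 2 kb window around peak 3053033 read [3052033, 3054033).

## Problem sizes in the test suite

The acceptance-style checks run entirely on synthetic data sized for a
single CPU: recovery at 500 peaks over 20 seeds, null calibration at 200
peaks over 100 seeds (rank uniformity is sample-size-independent, so the
null uses the smaller peak set), and size stability comparing 200 against
2000 peaks over 10 seed pairs. The brute-force oracles cover 500 random
descending matrices (r ≤ 8, b ≤ 5) and exhaustive 4^l enumeration for
l ≤ 6.

## Known limitations

* TRANSFAC dialect only; matrices with ambiguous-base rows have those
  rows dropped with a warning.
* The method needs peak *points*; broad-domain data (histone marks)
  violates the sharp-distance premise.
* S₁ and S₂ live on different scales; the default equal weights are a
  pragmatic choice, and per-dataset tuning of (ω₁, ω₂) — as one would do
  with labelled data — is left to the user.
* Scores are comparable between motifs on the same dataset, not across
  datasets with different n or m.
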