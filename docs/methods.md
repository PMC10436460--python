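# Methods

This note documents the models and procedures chromarch implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want spelled
out.

## Coordinate model

All coordinates are 0-based half-open; GFF3 input (1-based closed) is
converted on read. Chromosome order is the input order of the chromosome
table; bin ids are global and consecutive in (chrom, start) order, and the
last bin of a chromosome may be shorter than the bin size. Gene-to-region
assignment defaults to majority overlap with a leftmost tie-break; a
midpoint rule is available. Both are total and deterministic.

## Contact matrices and balancing

A contact matrix is one genome-wide symmetric sparse matrix (cis and trans
together) over a bin table, with a per-bin usability mask. Pair input is
filtered with a minimum cis distance of 4 kb (self-ligation and re-ligation
artifacts concentrate below that range); trans pairs are never
distance-filtered. Bins with zero cis coverage, or coverage below the 2nd
percentile of nonzero cis marginals, are masked; the threshold is the lower
order statistic so the operation is idempotent.

Iterative correction equalizes genome-wide unmasked marginals with the
symmetric (square-root) Sinkhorn update: each sweep divides the working
matrix by `sqrt(s_i/mean) · sqrt(s_j/mean)`. The square root matters — a
full-ratio update on a symmetric matrix divides every cell by the product
of two ratios and oscillates instead of contracting. Convergence is a max
relative marginal deviation below 1e-5 (configurable), within 200 sweeps,
else an error carrying the last deviation. The bias vector is normalized to
mean 1 over unmasked bins and the raw counts are always retained.

The map-resolution rule reports the smallest bin size at which ≥ 80% of
bins have ≥ 1000 incident contacts, counting pair endpoints (a self-pair
counts twice). It is monotone in sequencing depth by construction.

## Distance decay and Z-scores

The expected model pools all unmasked cis cells genome-wide per distance
stratum at the working bin size. Per stratum, zero cells are dropped
(`ignore_zeros`), values outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are dropped,
and the mean and standard deviation of the remainder are computed. Both are
then smoothed across strata by LOWESS with span 0.005 of the strata (the
window is floored at 3 strata so the local fit is defined on small maps),
applied in log–log space with no robustness iterations. The log–log choice
is deliberate: a power-law decay is locally linear there, so the smoother
nearly interpolates and the per-stratum standardization stays calibrated —
linear-space smoothing with robust reweighting biased stratum Z means by up
to ~0.1 at short range. Strata with no surviving observations, or a
(numerically) zero smoothed spread, are flagged invalid; cells in them are
excluded from the Z map rather than emitted as ±inf. A residual spread
below 1e-9 of the stratum mean is treated as exactly zero, so noiseless
maps do not leak round-off as signal.

Because the spread is estimated after outlier trimming, Z-scores on clean
Poisson data have a per-stratum standard deviation slightly above 1
(≈ 1.03–1.06); this sits comfortably inside the calibration band the tests
enforce ([0.9, 1.1]).

Difference maps are computed on Z-scores only, on the intersection of the
two validity masks; a cell valid in exactly one condition is reported
missing, not zero.

## A/B compartments

Called per chromosome on the balanced cis matrix at 100-kb resolution
(configurable). The observed/expected matrix uses the smoothed expected
mean; the self-interaction diagonal is excluded, and invalid cells are
filled with the neutral ratio 1 so they do not distort row correlations
(zero-filling makes the top two eigenvalues of a clean checkerboard nearly
degenerate and can let a shifted pattern win). Rows with fewer than 3 valid
cells, chromosomes with fewer than 10 usable bins, and rows without
numerical contrast are dropped or flagged NA. The per-bin score is the
projection of the column-centered correlation matrix onto its leading
principal axis, which makes scores exactly zero-mean per chromosome. The
sign is oriented per chromosome so the positive side has the higher mean
gene density — A is the active, gene-dense compartment. Orientation by GC
content would invert that convention in genomes where B is GC-richer, which
is why gene density is the default. Without a gene table, the sign is fixed
deterministically (positive at the highest-coverage bin) and labels should
be treated as unoriented.

Switch classification is a per-bin label comparison; contiguous
same-category runs are exported as regions, and the switching fraction is
switched bins over bins labeled in both conditions.

## TADs and transitions

The insulation score of bin i is the mean of the square of cells spanning
the w bins upstream by the w bins downstream of i (its own row/column
excluded), with w = 100 kb / bin size; it is computed with summed-area
tables and matches a brute-force double loop to 1e-12. A bin is valid only
when the full square fits inside the chromosome and ≥ 50% of the square's
cells involve unmasked bins. The normalized track is log2 of the ratio to
the chromosome mean.

The delta track is `mean(norm over (i, i+d]) − mean(norm over [i−d, i))`
with d = 40 kb / bin size, computed with NaN-tolerant window means (at
least half of each window must be valid) so isolated masked bins do not
punch holes in boundary detection. A boundary is placed at the first bin
where delta crosses zero upward. That bin is the domain junction: for two
abutting domains meeting between bins k−1 and k, the insulation valley
floor is a symmetric two-bin plateau {k−1, k} and the delta track is
antisymmetric around the junction, so the upcrossing lands on k
deterministically. (Snapping to the literal argmin of the valley is a
coin-flip between the two plateau bins under noise and was rejected.)
Boundary strength is the delta amplitude — max over the d bins right of the
crossing minus min over the d bins left — reported at ≥ 0.1.

TADs are the inter-boundary intervals including chromosome ends; intervals
shorter than 3 bins are dropped with a log note, and a boundary-free
chromosome becomes one flagged whole-chromosome TAD.

Transitions build a bipartite any-overlap graph between the two TAD sets
and classify each connected component: 1-vs-1 with reciprocal overlap
strictly above 0.75 for **both** TADs → Stable; 1-vs-k (k ≥ 2) with every
target at least 0.75 of its own length inside the source → Split; the
mirror case → Merge; everything else, including unmatched TADs,
→ Rearrangement. Both the Stable and membership thresholds are
configurable; reciprocal overlap is the default because it is symmetric and
the strictest reading. Every TAD of both conditions lands in exactly one
event, and swapping the condition order maps Split↔Merge exactly.

## Significant interactions

Cis pairs at distance ≥ 10 kb (all unmasked pairs, zero-count included) are
grouped into 100 contiguous equal-occupancy distance strata. The expected
count of a pair is the stratum rate times `b_i · b_j`, where the bias is
estimated inside the caller by alternating (a) stratum rates on
bias-corrected counts with (b) per-bin marginal matching against the
expected marginal, for 6 sweeps. The iterative-correction bias is *not*
reused here: it absorbs chromosome-edge coverage structure (end bins have
one-sided neighborhoods), which systematically deflates the expected at
chromosome ends and floods the Poisson tail with false calls. The
decay-matched estimate keeps the null fraction of p < 0.01 at ≈ 0.007 on
null maps with realistic bias while recovering planted 8× anchors at full
power.

P-values are Poisson upper tails `P(X ≥ count)`; q-values are
Benjamini–Hochberg over the whole tested family; a call is significant only
when `count > 2 AND p < 0.01 AND q < 0.01`. Trans pairs are tested against
`global trans mean × b_i · b_j`, with zero-count trans pairs entering the
BH family as implicit p = 1 tests. There is no second refinement pass.

Note the caller is a first-pass, stratified-Poisson test: on maps with real
compartment/TAD structure it flags structurally enriched cells as
significant, which is the intended behavior (those are real contact
enrichments over the decay null), and why structured maps yield thousands
of calls while pure-decay nulls yield none.

## Expression, DEGs and peaks

Class contrasts use the two-sided Wilcoxon rank-sum test (normal
approximation with tie correction) on log2(x+1) abundances; a fully tied
comparison returns p = 1 rather than NaN.

The differential-expression rule gates `|fold change| > 2 AND P < 0.01`.
Counts are normalized by median-of-ratios size factors (computed on genes
with all-positive counts) rather than totals: when a fifth of the genes are
differentially expressed in one direction, total-count normalization
absorbs the shift into the library size and compresses every fold change.
The log2 fold change uses pseudocount 1 on normalized means. The p-value
comes from a Welch t-test on log2-normalized counts when both sides have
≥ 3 replicates, and otherwise from the exact conditional binomial test on
summed counts (the classic two-sample Poisson comparison) with the
size-factor ratio as the null proportion — at 2 replicates a t-test has 2
degrees of freedom and cannot reach P < 0.01 at realistic effect sizes, so
the count-based exact test is the operative path there. Known limitation:
the exact test assumes Poisson counts; with overdispersed
(negative-binomial) data it is anticonservative for the p-gate alone
(~5–7% of null genes at P < 0.01 in the generator's conditions). The joint
fold-change gate keeps the final false-call rate low, but for real data a
dedicated DE model is the right tool; this rule exists to produce up/down
labels for architectural integration.

Region enrichment of DEGs is a two-sided Fisher exact test per region
category and direction (gene membership by midpoint); degenerate tables are
flagged with an undefined odds ratio. Peak gain/loss uses the any-overlap
rule — a condition-2 peak with zero bp overlap to every condition-1 peak is
a gain, the mirror a loss — assigned to the switch category of its
majority bin. Boundary metaprofiles average the per-bin peak coverage
fraction at offsets −10..+10 bins around boundary bins.

## Synthetic data

The generator draws each cis cell Poisson with rate

    λ(i,j) = B · (|i−j|·bin + d0)^(−α) · κ^[same compartment]
             · τ^[same TAD] · ρ^[loop pair] · b_i · b_j

and trans cells Poisson at a uniform background, κ-modulated for
same-compartment pairs. B is calibrated so the expected total equals the
requested depth; an infeasible depth raises. Defaults: 4 chromosomes × 2 Mb
at 10-kb bins, depth 5 × 10⁶ (~60 contacts per cis cell), α = 1, d0 = 10 kb,
κ = 1.5, τ = 2, ρ = 8, lognormal biases with σ = 0.1, trans background 0.05
per cell. Compartment blocks are 400 kb and alternate along each
chromosome; the domain tiling subdivides blocks so every block edge is also
a domain boundary — a κ step is itself an insulating discontinuity, so this
keeps "insulation valley" and "planted boundary" the same set. Chromosomes
are ≥ 20× the insulation window so validity margins are exercised.

Per-bin biases are drawn from their own seed, shared across conditions of a
study pair: they model sequence-driven effects (mappability, GC), which do
not change with treatment.

The default perturbation flips one interior block per chromosome, splits
one 400-kb domain and merges one 200+200-kb pair per chromosome, and swaps
one loop. Matched tracks place genes at 2× density in A, shift A-gene
abundance by +1 log2 and boundary genes by +0.5 log2, sample
negative-binomial counts (dispersion 0.1, mean depth 50 per gene, 2
replicates per condition), plant ±2 log2 DE effects on genes inside
switched regions, and drop Bernoulli peaks per bin with 2× A and 3×
boundary boosts for three marks per condition.

What the generator does **not** emulate: restriction-fragment structure and
read-level artifacts (dangling ends, PCR duplicates), distance-dependent
overdispersion of contact counts, nested/hierarchical domains, condition-
dependent biases, replicate Hi-C maps, and expression dependence on
anything other than compartment, boundary proximity and planted switches.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under the stated generative model, not performance on real
libraries.

## Pipeline determinism

Analysis stages are deterministic given inputs and configuration; the only
randomness in the package is in the generator, which is fully seeded.
The run manifest records the package version, a config hash and the sha256
of every output; file contents contain no timestamps or absolute paths, so
identical (inputs, config, seed) runs are byte-identical.

## Problem sizes used in validation

The test suite and the acceptance script run everything at desk scale: the
default 4 × 2 Mb study (800 bins, 5 × 10⁶ contacts), a 2 × 4 Mb
checkerboard at 100-kb bins for compartment recovery, 4 × 2.5 Mb null and
planted-anchor maps (~125 000 tested pairs) for the interaction caller, and
a 4000-chromosome × 40-bin i.i.d. decay map (~3 × 10⁶ cells, every pooled
stratum ≥ 4000 cells) for Z-score calibration — that last size is what
makes a ±0.05 band on per-stratum means statistically meaningful. The full
suite completes in about half a minute.
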