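# Methods

## The problem

Post-alignment quality control of single-cell ATAC-seq hinges on four
signal families: signal-to-noise enrichment (TSS enrichment, FRiP),
library complexity (total unique fragments), mitochondrial content, and
the fragment length distribution (FLD). In a healthy library the FLD is
periodic: a nucleosome-free peak near 50 bp followed by mono-, di-,
tri-nucleosomal peaks spaced roughly 200 bp apart, a direct footprint of
Tn5's steric exclusion around nucleosomes. At bulk resolution this
pattern is inspected visually; at single-cell resolution there are tens
of thousands of per-cell FLDs and a per-cell scalar is needed. `fldqc`
computes one: a wavelet-convolution periodicity score that grows roughly
linearly with pattern strength, so a single lower cutoff separates
high-quality cells, unlike ratio metrics (mNSC) that behave
non-linearly and need both a lower and an upper threshold.

## The periodicity score

For each barcode the pipeline is: histogram → downsample → convolve →
call peaks → mask-weight → sum.

**Histogram.** Fragment lengths (end − start of BED fragment records, or
template length of properly paired BAM reads) are binned at 1 bp over
[0, L_max], default L_max = 1000 bp, which covers through
tri-/tetra-nucleosomal lengths. Longer fragments are tallied as overflow
and excluded. The duplicate-count column of fragments files is honored
by default (`use_counts=False` gives unique-fragment histograms).
Mitochondrial exclusion is exposed as a chromosome denylist and left to
the caller, since contig naming is dataset-specific.

**Downsampling.** The raw score scales exactly linearly with histogram
depth (k-fold counts → k-fold convolution → k-fold peak amplitudes →
k-fold score), so depth must be normalised before scoring. Each
histogram with more than `target_n` fragments (default 5000) is replaced
by one multinomial draw of size `target_n` with probabilities
`counts/total`; this conserves the total exactly and gives every
sufficiently deep cell the same effective depth. Cells below the target
are scored as-is and flagged `below_target` — no upsampling, so very
shallow cells can receive artificially low scores; they are normally
removed by depth filters anyway.

**Wavelet.** The kernel is a cosine under a Gaussian envelope,

    psi_{a,b}(t) = cos(a(t−b)) · (1/(σ√(2π))) · exp(−½ (a(t−b))²/σ²),
    a = 2π/wavelength,

sampled on an integer-bp grid wide enough that edge values fall below
1e−8 of the peak (±60 bp at the defaults). Defaults wavelength = 150 bp
and σ = 0.4; σ is in *phase* units, so the effective envelope standard
deviation on the length axis is σ/a ≈ 9.5 bp. With these parameters the
kernel is a narrow, gently cosine-modulated bump with positive mean
(∫psi ≈ exp(−σ²/2)/a ≈ 22 bp), i.e. the convolution acts as matched
smoothing rather than as a zero-mean band-pass. Consequence: a constant
histogram convolves to a constant plateau, not to zero; featureless
inputs still score ≈ 0 because peak calling (below) only accepts strict
local maxima, and a plateau has none. Both parameters are config-exposed.

**Convolution.** Same-length, zero-padded (`numpy.convolve` mode
"same") — the histogram is naturally zero outside [0, L_max]. Agreement
with a direct shift-and-add oracle is asserted to 1e−9 in the tests.

**Peak calling.** Strict local maxima of the convolved signal (plateau
width 1) with positive amplitude; up to `n_peaks` = 5 peaks are kept,
selected greedily by descending amplitude with a minimum pairwise
separation of 100 bp (half the nucleosomal spacing); amplitude ties
break toward the smaller position, making results deterministic. The
plateau-width-1 rule discards degenerate flat maxima; exact floating
ties on real convolved signals are measure-zero.

**Scoring mask and score.** The expected pattern is encoded as a sum of
unit normal densities S(x) = Σᵢ wᵢ N(x; xᵢ, σ_mask) with default centers
{50, 200, 400, 600, 800} bp, σ_mask = 35 bp, uniform weights. The cell's
score is Σᵢ aᵢ·S(x′ᵢ) over called peaks (x′ᵢ, aᵢ). Peaks near expected
nucleosomal positions contribute fully; peaks elsewhere are suppressed
by the Gaussian tails (a peak 1 σ_mask off-center contributes e^(−1/2)
of its on-center value). The published per-component probabilities of
the original mask were derived from bulk data and are not public, so
uniform weights are the default and both centers and weights are
configurable; libraries with unusual architecture should adapt them.
The nucleosome-free ~50 bp component is included by default.

**Determinism and parallelism.** Each barcode's RNG is seeded from
(global seed, crc32(barcode)), so multi-worker scoring is bit-identical
to serial scoring regardless of scheduling. Per-cell failures become
flagged zero-score records; a batch never aborts.

## Companion metrics

* **mNSC** = (fragments 147–294 bp) / (fragments < 147 bp); 147 bp
  belongs to the mononucleosomal class, which partitions the two printed
  ranges cleanly. Undefined (NaN, fails any filter rule) when the
  denominator is zero. Being a ratio of two small counts it is highly
  unstable at low depth — the tests quantify this as a ~14-fold higher
  coefficient of variation at 20 vs 2000 fragments/cell.
* **TSSe**: full fragment bodies (not cut sites) are aggregated over all
  TSSs in a ±2000 bp window, strand-flipped for minus-strand sites; the
  score is the mean coverage in the central ±50 bp divided by the mean
  over the two outer 100 bp flanks. The denominator is floored at 0.1
  (aggregate-coverage units) so sparse cells stay finite and a
  zero-coverage cell scores 0. Whole-fragment coverage is one of several
  conventions in circulation; it is deterministic and matches the
  aggregate-fragments description the score family derives from.
* **FRiP**: fraction of a cell's fragments overlapping a peak by ≥ 1 bp
  (half-open intervals: an abutting fragment does not count). Peaks are
  merged before querying.
* **TC**: raw per-cell unique-fragment count including overflow — a
  pre-downsampling depth metric by contract.

## Distance score

A reference-free embedding-quality metric used to compare filter
settings. Feature sets are the sorted identifiers of a cell's nonzero
matrix entries; sorting fixes a deterministic serialization and makes
disjoint equal-length sets cost exactly n substitutions. The Levenshtein
distance between two cells' sequences is normalised by the larger
length, bounding it to [0, 1] (the alternative denominator, the summed
lengths, is supported in principle by the same wording but halves the
range; max was chosen and is the only documented behavior). For each
cell, its k nearest and k farthest cells in the embedding (Euclidean,
default k = 15, tie-break by barcode order) form two cohorts; the score
is mean(near) + 1/max(mean(far), ε) with ε = 1e−6 guarding
feature-identical datasets; the dataset score is the per-cell median.
Lower is better. "Distant cells" means the k farthest (a radius
criterion would need a dataset-dependent scale). Edit distance is
computed with `edlib` after mapping feature indices to code points;
tests verify it against an independent dynamic-programming oracle.

## Synthetic data

The generator emulates the statistical structure the methods respond
to, not genome biology. Per-cell lengths are drawn from

    p(x) = θ · Σⱼ wⱼ N(x; cⱼ, sdⱼ) + (1−θ) · Exp(x − 20; mean 250),

restricted to [20, 1000] bp by rejection, with centers (50, 200, 400,
600) bp, sds (15, 25, 35, 45) bp and uniform weights. θ interpolates
from pure noise to a fully periodic pattern; the exponential noise floor
mimics the short-fragment-dominated profile of degraded or apoptotic
material (a uniform floor would be unrealistically flat). Depth defaults
to 5000 fragments/cell, matching the downsampling target.

Fragments are placed on a toy genome (2 × 1 Mb chromosomes, 50 peaks of
500 bp, 100 TSSs on alternating strands) laid out so that peak intervals
and TSS ±2 kb windows never overlap, decoupling the FRiP and TSSe dials:
a `fraction_in_peaks` share of fragments is centred inside random peaks,
and for a TSS enrichment factor f > 1 a computed share is emitted as
101 bp fragments exactly covering a TSS ±50 bp so the expected
aggregate center/flank ratio equals f. The same placement can be written
as a sorted fragments BED or as a coordinate-sorted indexed paired-end
BAM encoding identical fragments, which the tests exploit to check both
readers against each other.

Embedding fixtures are 2-D Gaussian blobs (adjacent centers spaced by
`separation` on a circle) whose clusters own disjoint prototype feature
blocks; each cell keeps a `feature_overlap` share of its prototype and
fills the rest with cell-private identifiers.

What passing tests on this generator do **not** show: robustness to
doublets, batch effects, barcode errors, chimeric fragments, or
cell-type-dependent FLD strength in real tissue — none of which are
modelled.

## Problem sizes and numerical choices

The statistical checks run at the sizes the properties are stated for:
monotonicity uses 100 cells × 5000 fragments per θ ∈ {0, 0.25, 0.5,
0.75, 1}; depth invariance uses 200 cells/arm at 10× and 100× the
5000-fragment target; downsampling marginals use 500 seeds; mNSC
stability 500 seeds at 20 vs 2000 fragments; distance-score shuffling 50
permutations of a 20-cell two-blob fixture. A binomial 99.9% interval
over 500 draws is allowed ≤ 4 exceedances (P > 4 under the null is
below 1e−4). Convolution agreement is asserted at atol 1e−9; analytic
kernel/mask values at 1e−9 using single-center masks so closed forms
hold without neighbor-tail corrections.

## Known limitations

* The scoring-mask weights are uniform, not the (unpublished)
  bulk-calibrated probabilities of the original method; absolute score
  values are therefore not comparable to other implementations, only
  orderings and thresholds calibrated on the same configuration.
* Cells below the downsampling target are flagged but still scored;
  their scores are depressed and should be interpreted jointly with a
  depth filter.
* TSSe is quadratic-free but loops over TSS × overlapping fragments;
  for genome-scale annotations a binned implementation would be faster.
* The distance score is O(n·k·L²) in cells × cohort × feature-set
  length; the `top_m` cap trades fidelity for tractability on wide
  matrices and is off by default.
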