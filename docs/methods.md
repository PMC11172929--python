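# Methods

## Statistics

**Nucleotide diversity.** Per site, π is the mean pairwise difference among
called haplotypes, c_alt·c_ref / C(n, 2); per window it is the sum of site
values divided by the window span in bp, so invariant positions dilute the
estimate through the denominator, matching the windowed-π convention of
standard VCF tooling. Windows are 0-based half-open, 100 kb wide with a
50 kb step by default (overlapping), with trailing partial windows emitted
and identifiable by their span.

**Weir–Cockerham F_ST.** The two-population variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are computed per site from the per-population called sample
sizes, allele frequencies and observed heterozygosities, exactly as in the
1984 estimator. The windowed statistic is the "weighted" ratio of sums
Σa / Σ(a+b+c); a mean-of-ratios variant is also exposed for comparison.
Negative values are retained — clamping them would bias the empirical null
that the Z-transformation builds. Sites where either population has no
called genotype, or where the mean sample size is 1, are skipped.

**Pooled heterozygosity.** Hp = 2·Σn_MAJ·Σn_MIN / (Σn_MAJ + Σn_MIN)², with
per-site major/minor *allele counts* (not frequencies) summed over the
window. Bounded by 0 and 0.5; depressed where a sweep has homogenised the
test population.

**Tajima's D.** D = (π_sum − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
constants derived from the number of sampled haplotypes n. With missing
data the per-site called count varies; the constants use the rounded mean
called count over the window's segregating sites (exact when data are
complete). Windows with S < 2, n < 4 or a non-positive variance term are
flagged rather than forced to zero.

**Missing data policy.** Every statistic uses per-site called allele
counts; genotypes are never imputed (the single exception is PCA, below).

## Selection scan

Z-scores are computed once over all finite window values genome-wide
(population-sd convention), not per chromosome, giving a single empirical
null. The empirical tails flag exactly ceil(q·W) windows at q = 0.005,
with W the number of windows carrying a finite statistic and ties at the
cutoff broken by genomic order, so reruns are byte-identical. Windows with
fewer than 10 SNPs are excluded from the null rather than contributing
noise-driven extremes.

The π-ratio statistic is ln(π_test/π_ref) with the reference diversity
computed on the pooled reference samples; its *lower* tail is selected
because a sweep depresses test-population diversity (a `ratio_tail` switch
flips the convention). Windows with zero diversity in either term are
flagged and excluded from the tails instead of propagating ±∞.

Flagged windows are merged into maximal overlapping/book-ended regions; a
gene is hit when it overlaps a region by at least 1 bp in half-open
arithmetic (no minimum-overlap rule is imposed), protein-coding biotypes
only by default. The three-method intersection and full Venn pattern counts
are reported per gene.

## Diversity and structure

**ROH.** A 50-SNP sliding window is homozygous-eligible when it contains at
most 1 heterozygote and 2 missing calls; a SNP joins a candidate run when
more than 5% of the windows covering it are eligible. Because this vote
blurs run edges by a couple of SNPs, final segment boundaries are refined
to the surrounding heterozygote-free stretch: runs extend outward through
non-heterozygous calls, split at any interior heterozygote, and trim to
homozygous calls at the ends. The refinement makes planted-tract recovery
exact to one inter-SNP gap; its cost is that a single genotyping-error
heterozygote splits a long run (conservative relative to callers that
tolerate interior heterozygotes). Segments need ≥ 50 SNPs, ≥ 0.5 Mb and
≥ 1 SNP per 50 kb, and are classified into 0.5–1 Mb, 1–2 Mb and >2 Mb.

**LD.** r² is the squared Pearson correlation of unphased genotype dosages
(the composite measure) over jointly-called samples — the data are
unphased, so haplotype-based r² is out of reach by design. Decay curves
bin all intra-chromosomal pairs within 500 kb (1 kb bins by default).
Pruning follows the greedy 50-SNP-window / 10-SNP-step / r² > 0.2 scheme
and repeats passes until stable, which guarantees the post-condition that
no surviving in-window pair exceeds the threshold.

**PCA.** Sites are centred by 2p̂ and scaled by √(2p̂(1−p̂)) (Patterson
convention); missing dosages are mean-imputed per site before projection —
the simplest defensible policy, stated here because nothing in the data
model forces it. Eigendecomposition of the sample-by-sample covariance
yields unit-norm coordinates and percent variance per component.

**Distances and tree.** IBS between two samples is the mean allele-sharing
proportion (2 − |dosage difference|)/2 over jointly-called sites; the tree
is Saitou–Nei neighbour joining on 1−IBS with the standard Q-criterion and
branch-length formulas, serialised as a trifurcating unrooted root.
Negative branch lengths are clamped to zero with a warning. On additive
matrices NJ reconstructs the generating tree exactly, which the test suite
exploits as an oracle. Population-level trees average 1−IBS over
cross-population sample pairs; a run with fewer than three populations
falls back to a sample-level tree.

## Synthetic data

Two generators cover the two kinds of signal the statistics need.

**Balding–Nichols** draws an ancestral frequency p ~ Uniform(0.05, 0.95)
per site and a population frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), so
the per-site population-frequency variance is F·p(1−p) and F is the
expected Weir–Cockerham F_ST — closed-form divergence for estimator
recovery. Genotypes are Binomial(2, p_pop); sites monomorphic in the whole
sample are dropped (they are not variants); missingness is i.i.d. per call.

**Wright–Fisher** starts from stationary neutral standing variation (the
expected number of sites with derived count i of 2N is θ_L/i), drifts each
daughter population independently by per-generation binomial resampling
with new mutations entering at 1/(2N), and draws diploid samples at the
end. An optional hard sweep first simulates the beneficial-allele
trajectory p' = p(1+s)/(1+ps) with binomial noise, conditioned on fixation
by restart (budget 1,000; exhaustion raises an error rather than failing
silently). Its effect on linked sites uses the star-like hitchhiking
approximation: a site at distance d escapes with probability
1 − exp(−(r·d/s)·ln 2N); each allele rode the sweeping haplotype with
probability equal to its frequency, and the post-sweep frequency is
b(1−e) + e·p. Near the sweep this drives frequencies toward 0 or 1 — the
U-shaped spectrum that produces the diversity trough, the F_ST peak, the
Hp deficit and negative Tajima's D that the scan detects. The recorded
truth interval is the span where the escape probability is below one half,
d ≤ s·ln2 / (r·ln 2N).

Default conditions mirror the targeted study design: three populations of
10 diploid samples (one test, two references), F = 0.12 for the
frequency-model divergence. The mechanistic model runs at a rescaled
diploid N = 100 with μ = 5·10⁻⁷/bp (θ = 4Nμ = 2·10⁻⁴/bp) and r = 10⁻⁸/bp,
a split of 20 generations, and sweeps at s = 0.1: parameters chosen once so
that diversity, divergence and sweep footprints are on realistic relative
scales while a 100 Mb chromosome (≈ 2,000 sliding windows, ~10⁵ SNPs)
simulates in seconds. What the generator does *not* emulate: recombination
within the neutral background (sites drift independently), linkage beyond
the sweep's star-like footprint, demographic change, genotyping error
structure, and reference-bias artefacts. Passing recovery tests therefore
show estimator and pipeline correctness under the stated models, not
robustness to every property of real sequencing data.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open everywhere; VCF/GFF3 convert
  at the I/O boundary; `GeneModel` keeps its GFF3 1-based inclusive
  coordinates and converts on the fly for interval arithmetic.
- MAF filtering is inclusive (a site at exactly the threshold is kept);
  the comparator is exposed in `FilterConfig`.
- Z-transformation with zero spread is a hard error; flagged (NaN) windows
  pass through untouched.
- An all-sites-removed filter result is a warning and an empty matrix, not
  an error.
- Tail selection, window merging, LD pruning and NJ joining are all
  deterministic given input order (documented tie-breaks), so pipeline
  reruns are byte-identical; the manifest records a config hash, seed and
  per-stage row counts.

## Problem sizes used by the checks

The test suite and acceptance script run Balding–Nichols recovery at
10,000 SNPs × 50 diploids/population, neutrality at 5 Mb / 50 windows,
end-to-end sweep recovery at 100 Mb (≈ 2,000 windows, ~1.2·10⁵ SNPs) over
10–20 seeds, and the combinatorial checks (tails, NJ, pruning, ROH, PCA)
at enumerable sizes — chosen as the smallest scales at which the studied
effects are unambiguous.
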