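# Methods

This note documents the models, conventions and numerical choices behind
`sporekit`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and
where a convention had to be chosen because the field has more than one.

## Coordinates and data model

All coordinates are 0-based half-open internally; VCF, GFF3 and
RepeatMasker coordinates are converted exactly once, at the file boundary.
Haploid genotypes are stored as a samples × sites integer matrix (A,C,G,T →
0..3, missing → −1). Only biallelic SNPs are retained at read time:
multi-allelic records and indels are dropped (and counted) because the
downstream p-distance treats alleles categorically and window information
content should be homogeneous. Site filtering removes (a) any site inside a
repeat annotation (interval-tree lookup) and (b) any site missing in any
sample; the filter is idempotent and sample order is preserved.

Two windowing schemes exist. *Variable-site windows* contain exactly
`n_sites` (default 50) variable sites; the trailing partial window is
dropped, since a window with fewer sites would carry less phylogenetic
information and bias the scan's support values. *Fixed windows* of `size`
bp at every `step` bp start at 0 and are emitted only when they fit
entirely on the chromosome, so `step == size` tiles the chromosome prefix
disjointly.

## Window trees and the monophyly scan

**Distance model.** Within a window, d(i,j) is the proportion of differing
sites (p-distance) and the BioNJ variance matrix is initialized to the
distance itself (the Poisson-like choice). A Jukes–Cantor correction is
available behind a flag but off by default: on 50-site windows it is
undefined whenever a pair differs at ≥ 3/4 of sites, and the scan only
consumes tree *topology*.

**BioNJ.** At each step the pair minimizing
Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k) is joined. Branch lengths
follow the standard NJ formulas; the reduced distance uses the mixing
weight λ = 1/2 + Σ_k (v(j,k) − v(i,k)) / (2(r−2)·v(i,j)), clamped to
[0, 1], with λ = 1/2 when v(i,j) = 0 or r = 3; reduced variances are
v(u,k) = λ·v(i,k) + (1−λ)·v(j,k) − λ(1−λ)·v(i,j). Ties in Q are broken by
the smallest index pair, which makes the build deterministic across
platforms. Negative branch lengths are clamped to zero in the *stored*
tree only; the raw values feed the reduction, which keeps the algorithm
exactly additive-consistent and exactly equal to plain neighbor joining
when the variance matrix is identically zero. Note that an all-*equal*
(nonzero) variance matrix does not keep λ at 1/2 beyond the first join:
the variance reduction deliberately makes merged nodes lower-variance,
which is the point of BioNJ. The zero-variance matrix is therefore the
degenerate case used for NJ-equivalence checks.

**Rooting.** Monophyly is only defined on a rooted tree. The tree is
rooted on the designated outgroup set: if the outgroup forms a split of
the unrooted tree, the root is the midpoint of its stem edge; otherwise
(outgroup not monophyletic in that window) the tree is rooted on the
terminal edge of the lexicographically first outgroup id, with a warning —
a deterministic fallback that keeps the focal-clade call well defined even
when the outgroup placement is unreliable.

**Classification.** Without an anchor, a window's category is the leaf set
of the largest clade *of at least two leaves* whose leaves all belong to
the focal set; ties on size are broken by the lexicographically smallest
sorted id tuple (a convention — real data rarely produces exact ties). If
no two focal strains group together the category is empty. The ≥ 2-leaf
rule is a deliberate choice: a singleton "clade" carries no grouping
information, and it gives the degenerate all-identical window a natural
empty call. With an anchor (a second driver type whose relationship to the
focal set is being probed), the category is the focal subset of the
*smallest* clade containing the anchor whose leaves lie within
focal ∪ {anchor} — the innermost grouping that joins the anchor to focal
strains.

**Bootstrap.** Support is the fraction of site-resampling replicates whose
tree yields *the same category as the original window* (not the best
category per replicate). Each window draws its own stream from
(seed, window index), so per-window results are reproducible regardless of
how much of the chromosome is scanned. Default 100 replicates.

**Summaries.** Calls are binned (default 50 windows per bin) into category
proportions; the final partial bin is reported at its actual size. The
pairwise divergence scan counts differing variable sites between two named
samples per fixed window (default 10 kb / 2 kb) divided by window length
in bp — a per-bp rate, deliberately not a per-variable-site rate, so
repeat-poor and repeat-rich stretches are comparable.

## Repeat and chromatin windows

Repeat fraction per 2-kb window is computed on the *union* of repeat
annotations (overlap-merged), so it is invariant to annotation order and
splitting. Windows with repeat fraction strictly greater than 0.75 are
"repeat windows" (exactly 0.75 is non-repeat). GC ignores N. Percent
methylation is the fraction of covered cytosines whose methylated/total
read ratio is ≥ 0.5 (configurable; a read-weighted mode is available);
windows with no covered cytosine are NaN and excluded from means. IP fold
is mean IP depth over mean input depth, NaN when input is zero.

Group comparisons default to the pooled-variance Student's t (Welch behind
a flag), returning per-group mean ± 1.96·SE intervals for plotting. Repeat
family enrichment is an upper-tail binomial test per family — k = family
bp in the region, n = region length, p0 = genome-wide family fraction —
with Bonferroni-corrected significance across tested families. Base pairs
are not independent draws, so these p-values are calibrated for ranking
rather than literal error rates; a per-annotation-count unit is available.
The region-vs-genome comparison takes sliding genome windows of exactly
the region's size and reports the empirical 2.5/97.5 percentiles (linear
interpolation) — an empirical band, chosen over a normal approximation
because window statistics of repeat content are strongly skewed.

## Coding-sequence diversity and divergence

Counting follows Nei–Gojobori (1986) with equal pathway weighting.
Per-codon site counts exclude mutations to stop codons from both numerator
and denominator, so N + S = 3 for every sense codon (Phe TTT → N = 8/3,
S = 1/3). Pairwise codon differences average the synonymous/nonsynonymous
split over all minimal mutational pathways, excluding pathways through
stops (with an all-pathways fallback in the rare case every ordering is
blocked); the two counts always sum to the Hamming distance.

Per gene: π_N is the mean over ingroup pairs of nonsynonymous differences
per nonsynonymous site (sites averaged over the pair), π_S likewise, and
π_total is mean pairwise differences per alignment bp. Codons with
ambiguity or stops in either member of a pair are excluded for that pair.
Polymorphism counts (P_N, P_S) count each segregating codon's changes
against the column's majority codon. Divergence (D_N, D_S) uses fixed
differences only: codon positions where the ingroup is monomorphic, the
outgroup is monomorphic, and the two codons differ; positions polymorphic
in either group contribute to P, not D — the standard McDonald–Kreitman
bookkeeping.

Region aggregation keeps per-pair sums, so pooled π is mathematically
identical to recomputing on the concatenated alignment (verified against a
concatenation oracle). NI = (P_N/P_S)/(D_N/D_S) on pooled counts; NI > 1
indicates segregating weakly deleterious variation (relaxed/negative
selection), NI < 1 an excess of fixed nonsynonymous change. Genes
straddling the region boundary are assigned by CDS midpoint (logged).

**Bootstrap null.** Each replicate draws the region's gene count from the
background with replacement and pools. Count statistics are rescaled by
region length / total sampled gene length so they are comparable to the
region's totals; ratio statistics are scale-free and left alone. The 95%
interval is the 2.5/97.5 percentile band and the empirical two-sided
p-value is 2·min(r, 1−r) with r = (1 + #{replicates ≤ observed})/(reps+1),
which is never exactly zero.

**Age bound.** For each region gene, synonymous divergence dS is computed
against every member of the recombining sensitive panel and the minimizing
partner kept; pooled dS = Σ s-differences / Σ S-sites over genes, and
age = dS/(2µ). Because the panel recombines, no single strain is uniformly
closest; taking per-gene minima therefore under-counts divergence and
makes the estimate a lower bound. The substitution rate µ
(subs/site/year) is a required configuration parameter with no default —
it is a property of the study system, not of the method.

## The synthetic generator

The generator emulates a multi-strain haploid fungus: a set of sensitive
strains, a clade of driver strains whose non-recombining region sits on
one chromosome, one deeper lone driver of a second type, and an outgroup
species. There is no coalescent machinery: genealogies are fixed and
per-branch mutation counts are Poisson(branch length × bp), placed
uniformly at unused positions (infinite sites). This keeps every
expectation analytic — e.g. the expected distance between two sensitives
is exactly 2θ — at the cost of realism in genealogical variance. Outside
the region all ingroup strains hang off one star (the drivers having been
backcrossed into the sensitive background); inside it, the driver-A clade
has its own stem.

Defaults (chosen once as the study conditions): 9 sensitive + 4 driver-A +
1 driver-B + 2 outgroup samples; θ = 0.002 substitutions/site within
groups; driver stem 0.03 (an order of magnitude deeper than within-group
diversity, as in old drive haplotypes); outgroup stem 0.06; a 35-kb region
on a 120-kb chromosome, sized so one replicate carries ≈ 5,000 variable
sites (≈ 100 scan windows); repeat clusters at GC 0.30 in a 0.50 genome;
cytosine methylation 0.9 in repeats vs 0.02 outside at ~20× depth; 6-fold
IP enrichment over input in repeats.

Introgression tracts copy the sensitive consensus (the reference allele)
into a named driver sample over an interval, which is what a double
crossover with the recombining background looks like in a SNP matrix.
Coding variation is planted mutation-by-mutation with exact NG86
classification, at most one mutation per codon, polymorphisms on random
proper subsets of the ingroup and divergences fixed in the outgroup —so
the planted (P_N, P_S, D_N, D_S) are recovered *exactly* by the analysis,
which is the basis of the parameter-recovery tests. Genealogy mutations
avoid CDS so they cannot contaminate the planted counts.

What the generator does **not** model: recombination within groups, gene
conversion, RIP-like mutation spectra, TE sequence structure, indels,
sequencing error and missing data patterns. Passing tests on this data
therefore demonstrates that the *procedures* are correct (windows, trees,
classification, counting, pooling, resampling), not that the statistical
power claims transfer to any particular real dataset.

## Numerical and degenerate-case choices

- All-identical windows produce an empty monophyly category with undefined
  support rather than an arbitrary tree-shaped artifact.
- Zero pooled variance in the t test: equal means → t = 0, p = 1; unequal
  means → p = 0 with a degeneracy flag.
- NI is refused (with a reason) when P_S, D_N or D_S is zero, rather than
  returning infinities.
- Genes with a spliced CDS length not divisible by 3, or with internal
  stops, are flagged invalid and skipped with a log message.
- Bootstrap replicate streams derive from (global seed, window index) or
  the stage seed, so stage-level reruns reproduce pipeline-level results;
  the simulator writes byte-identical output for identical seeds.

## Problem sizes

The bundled verification suite runs entirely on generated data at small
scale: 100 random trees of ≤ 8 taxa for the BioNJ oracle, 200 random
rooted trees of ≤ 10 leaves for the classifier oracle, 100 simulated
region replicates (~5,000 variable sites each) for tract recovery, 200
outer replicates for bootstrap coverage, and exhaustive enumeration over
all 61 × 61 sense-codon pairs. These sizes were chosen as the smallest
that make the pass/fail criteria statistically meaningful.
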