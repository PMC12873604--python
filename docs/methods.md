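# Methods

## The analysis in one paragraph

Full-length (> 6 kb) evolutionarily young L1 retrotransposons (L1HS, L1PA2,
L1PA3) carry an intact internal 5′ promoter and are kept silent in somatic
cells by SETDB1-deposited H3K9me3 heterochromatin and promoter CpG
methylation. The pipeline quantifies what happens when that repression is
removed: which called peaks disappear, which individual TE loci become
transcriptionally active, whether the activated loci are concentrated in
particular TE families, whether their transcription is sense-stranded (i.e.
initiated from the element's own promoter), and how their promoter 5mC/5hmC
status changes.

## Coordinates and catalogs

All internal coordinates are 0-based half-open; GTF input/output converts at
the boundary (1-based inclusive). A TE catalog is parsed from the
TEtranscripts GTF dialect (`gene_id` = subfamily, `transcript_id` = locus,
`family_id`/`class_id` = repeat family/class); classes are normalized onto
{L1, Alu, ERV, SVA, other}. Evolutionary age ranks come from a packaged
subfamily table (L1HS = 0, L1PA2 = 1, ...); subfamilies absent from the table
get a large sentinel rank so "young" comparisons stay monotone. Full-length
status is strict: an L1 is full length iff its span exceeds 6000 bp.
Promoter windows are the 5′-most 1000 bp of an element (clipped to the
element); the L1 5′ UTR that contains the bidirectional promoter is ~900 bp,
and no more precise published extent exists, so 1 kb is the default and the
length is a parameter everywhere it is consumed.

## Peaks

Called peaks are inputs. The post-filter keeps peaks strictly longer than
500 bp on chr1–22, X, Y (the reference set is configurable; the analysis
convention "reference chromosomes" is not an enumerated list anywhere
authoritative). Peak→TE assignment gives each peak the class of its
best-overlapping element; ties break by larger overlap, then younger
element, then leftmost — an arbitrary but deterministic rule. A control peak
is *retained* iff it overlaps any treatment peak by ≥ 1 bp; `fraction_lost`
is the complement. The 1 bp criterion is the simplest overlap reading of
"peak loss" and is exposed should a stricter reciprocal-overlap rule be
wanted.

Signal matrices mimic the usual heatmap-matrix computation: reference-point
mode anchors at the strand-aware 5′ end with upstream/downstream flanks;
scale-regions mode linearly rescales the body into a fixed number of bins.
Minus-strand rows are reversed so bin 0 is always 5′-most. Tracks are
bedGraph (text); positions without data contribute 0. k-means over matrix
rows is Lloyd's algorithm with k-means++ seeding, 10 restarts and at most
300 iterations, all driven by one seeded generator; the per-iteration
inertia trace is kept so the non-increase invariant is testable. The
"promoter confidence" call replaces a by-eye browser curation step with a
reproducible threshold: background is the 0.75 quantile of all matrix bins,
"high" means the mean promoter-side signal reaches 5× background, "low"
anything above background but below that, "none" otherwise. Both parameters
are exposed; the point is determinism, not replicating any specific manual
count.

## Resampling enrichment

Let T be the catalog size, N the number of activated loci, K_g the catalog
count of group g (class or subfamily — both groupings are supported). Each
of R replicates draws N loci uniformly without replacement from the full
catalog and counts per group; the joint group counts of such a draw are
multivariate hypergeometric over the K_g, which is how the replicates are
actually sampled (vectorised, one seeded generator). The score for g counts
replicates whose sampled count strictly exceeds the observed one — ties fall
on the non-exceeding side, mirroring a "+1 if expected > observed, else +0"
scoring rule. Then

    p_one = (score + 1) / (R + 1)
    p_two = min(1, 2 * min(p_one, 1 − p_one))

The add-one form avoids p = 0 at score 0 and is the standard conservative
empirical estimator; doubling the smaller tail is the conventional
double-sided construction where no explicit formula is prescribed. The
default R is 50 000; calibration suites run at R = 2 000–10 000. The
resampling universe is the full parsed catalog (all loci, not only full
length); restricting it is a caller decision. One group's count under a
single draw is Hypergeometric(T, K_g, N); `hypergeometric_oracle` (scipy,
log-space survival function) is the exact reference the Monte-Carlo tails
are tested against, never the implementation of the statistic itself.

## Expression

Size factors are gene-derived median-of-ratios: with reference_i the
geometric mean of gene i across samples over genes positive in every
sample, factor_j = median_i(count_ij / reference_i), with no post-hoc
rescaling — so tests compare factors after geometric-mean alignment, which
removes the common scale. DE tables are consumed, not computed: the
upstream differential-expression engine is out of scope, and the synthetic
generator emits a truth-consistent table so the downstream selection logic
is testable in isolation. Selection rules are literal: TE up-regulation is
LFC > 0 (strict) and padj < 0.05 (strict, missing padj excluded); DE genes
are |LFC| > 1 (strict) and padj < 0.05; detectability is baseMean ≥ 1
(inclusive). Mean-plot values are log2(mean normalized count + 0.5) per
condition.

Mann–Whitney U uses the exact null when both groups are ≤ 8 and tie-free,
otherwise the normal approximation with continuity and midrank tie
correction (scipy's implementation; an independent exhaustive enumeration
is the test oracle). Group comparisons treat each L1 locus as one
independent replicate, with one value per locus per condition. The
proximity analysis calls a gene proximal when its span lies within 50 kb
(default, configurable — the underlying published threshold is not stated)
of any full-length young L1, and compares proximal vs distal LFC
distributions with the same test.

## Methylation

Interchange is bedMethyl-style text (chrom, start, end, mod code m/h,
coverage, strand, modified-call count); modified-BAM parsing is upstream
tooling and out of scope. Promoter fractions are coverage-weighted:
Σ n_mod / Σ n_valid over in-window sites with coverage ≥ 4 (default; a
small floor that stabilises per-window fractions, not a published value).
Windows with no qualifying site are *undefined* and excluded from
comparisons, with the exclusion count reported. Composite profiles place
each site at its relative 5′→3′ position within its element ((pos −
start)/len on +, (end − 1 − pos)/len on −) and average coverage-weighted
fractions per bin and condition; linear length scaling replaces
consensus-sequence realignment, preserving the promoter-vs-body contrast
that matters while avoiding an external aligner. When more than 200
elements are supplied, a seeded uniform subsample of 200 is used, matching
the conventional per-plot cap. Paired condition comparisons drop zero
differences, use midranks of |d|, take W = min(W+, W−), and compute the
two-sided p by exhaustive sign-pattern enumeration for n ≤ 12 (exact even
with tied magnitudes) or the normal approximation with continuity and tie
correction above; identical conditions (all differences zero) return p = 1
rather than erroring inside the comparison wrapper.

## Synthetic data

The generator is the package's test bed and defines its study conditions.
Defaults: 3 chromosomes × 10 Mb; ~1 900 TE loci in an L1-heavy composition
(truncated L1HS/PA2/PA3/PA4/PA7, AluY/AluSx, two ERV families, SVA_A/B,
MIR) plus 60/60/60/40 full-length L1HS/L1PA2/L1PA3/L1PA4 loci of 6 001–7 000
bp; 2 000 genes; 2 control + 2 treatment samples with depth factors (1.0,
0.8, 1.2, 1.0). Elements and genes are placed without overlap by Dirichlet
gap sampling, keeping 150 kb chromosome-end margins free so the ectopic
treatment blocks (100 kb at both ends of every chromosome) sit on otherwise
empty sequence.

Control peaks cover every young full-length L1 (± up to 1 kb jitter) plus
500 background peaks of 0.6–3 kb; candidate peaks are trimmed to be
mutually disjoint, as a peak caller's output would be, and each is then
independently deleted in treatment with probability 0.85. Because peaks are
disjoint within the control set, the ≥ 1 bp retention estimator recovers the
realized binomial loss fraction exactly; the residual spread of the
estimate around 0.85 is binomial noise (≈ ±1.4% SD at ~650 peaks).

Counts are negative binomial (dispersion 0.1) with per-sample depth
factors; 90% of genes are non-DE, the rest get |LFC| ~ U(1, 3). A seeded
30% of young FL-L1s are activated: treatment mean shifted by 3 log2 units
with sense share 0.8 (others 0.5 everywhere — the sense bias manifests
where activation acts). The emulated DE table carries true LFC + N(0, 0.3)
noise, padj < 0.01 at planted loci and padj ~ U(0.1, 1) elsewhere, with
pvalue ≤ padj by construction. Methylation covers full-length L1 loci:
CpG sites every 150 bp, coverage ~ Poisson(15) (min 1), per-element latent
5mC levels Beta(17, 3) in control (mean 0.85) dropping to Beta(4, 6)
(mean 0.40) at activated loci in treatment; 5hmC means 0.02 → 0.10 with
concentration 100. A promoter-signal track plants "high" amplitude at
activated loci and a weak "low" tier at 15% of the remaining young FL-L1s,
with U(0.1, 0.2) background noise, as ground truth for the confidence call
and the k-means clustering.

What the generator does *not* emulate: mappability and multi-mapping
artifacts (the dominant real-world difficulty of locus-level TE
quantification), genomic clustering of repeats, sequence-level signal,
correlated DE noise, or a real DE engine's shrinkage behaviour. Passing
tests therefore demonstrate that the analysis logic is correct under the
assumed statistical structure, not that the thresholds would behave
identically on real alignments.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen as desk-scale
study conditions: enrichment calibration at R = 2 000 over 500 null draws
(the analytic rejection rate of the two-sided empirical p at α = 0.05 for
the focal L1 class, T = 1900, K = 720, N = 150, is 0.054, so the accepted
band [0.03, 0.08] brackets the truth); Monte-Carlo tail checks at
R = 10 000 against the exact hypergeometric tail within 4 standard errors;
power at 100 seeded runs of a 10-fold young-L1 sampling bias (N = 60,
R = 2 000), where the planted signal is many null SDs from the mean so
p_two bottoms out at 2/(R+1). Size-factor recovery uses 2 000 genes and
depths (1.0, 0.5, 2.0, 1.5); the median-of-ratios error there is ~1%,
comfortably under the 3% acceptance bound. All randomness flows through
`numpy.random.default_rng` with explicit seeds; derived seeds stay below
2³¹. Ties in k-means (empty clusters) keep their previous centroid;
degenerate inputs (empty peak sets, all-zero differences, windows without
sites) raise or mark undefined explicitly rather than returning silent
zeros.

## Known limitations

- The manual-curation replacement (promoter confidence) is a thresholded
  stand-in; it is not expected to reproduce any published curated count on
  real data.
- The composite profile's linear length scaling ignores indels relative to
  a subfamily consensus; profiles of heterogeneous-length elements blur
  accordingly.
- The retention criterion (≥ 1 bp) is generous on real, fragmented peak
  sets; a reciprocal-overlap variant would be stricter and is not currently
  implemented.
- Empirical p-values are bounded below by 1/(R+1); family-level conclusions
  at very small p are statements about the resampling resolution, not about
  the analytic tail.
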