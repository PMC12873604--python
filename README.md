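# telocus

Locus-level analysis of transposable-element (TE) regulation after loss of
heterochromatin, built around the question: *when the repressive H3K9me3 mark
is removed (e.g. by CRISPRi silencing of the methyltransferase SETDB1 in
human neural progenitor cells), which individual TE loci wake up, and what
happens at their promoters?*

The package is aimed at epigenomics analysts working with CUT&RUN peak sets,
locus-level RNA-seq count matrices and nanopore-derived CpG modification
calls. It implements, as composable library functions with a thin CLI:

- **TE/gene catalogs** — TEtranscripts-dialect GTF parsing (gene_id =
  subfamily, transcript_id = locus), full-length classification (L1 > 6 kb,
  strict), evolutionary-age ordering (L1HS youngest), 5′ promoter windows,
  reference-chromosome filtering.
- **Peak analysis** — post-filtering of called peaks (length > 500 bp on
  chr1–22/X/Y), sweep-line interval intersection, peak→TE-class assignment
  by maximal overlap, control→treatment peak retention, binned signal
  matrices (reference-point and scale-regions, strand-aware), seeded k-means
  clustering of promoter signal, and a thresholded promoter-signal
  confidence call.
- **Resampling enrichment** — the observed-vs-expected family statistic:
  draw the observed number *N* of activated loci uniformly without
  replacement from the annotation, score each of *R* replicates +1 when the
  sampled family count exceeds the observed one, and report
  `p_one = (score + 1) / (R + 1)` with the two-sided p doubling the smaller
  tail (default R = 50 000). A single family's count under one draw is
  exactly Hypergeometric(T, K, N), which the package exposes as an analytic
  oracle.
- **Stranded expression** — gene-derived median-of-ratios size factors
  (factor_j = median over all-positive genes of count_ij divided by the
  gene's geometric mean), DE-table selections (TE up: LFC > 0 & padj < 0.05;
  genes: |LFC| > 1 & padj < 0.05; detectable: baseMean ≥ 1), mean-plot
  values log2(mean + 0.5), sense/antisense summaries, Mann–Whitney U
  comparisons (each locus an independent replicate), and TE-proximal gene
  analysis.
- **Promoter methylation** — bedMethyl-style 5mC/5hmC per-CpG calls
  aggregated into coverage-weighted promoter fractions, length-scaled
  composite profiles (seeded cap of 200 elements), and paired
  control-vs-treatment Wilcoxon signed-rank tests.
- **Synthetic data** — a fully seeded generator that plants every signal the
  analysis is supposed to find (85% peak loss plus ectopic chromosome-end
  blocks, sense-biased activation of a fraction of young full-length L1s,
  promoter 5mC loss and 5hmC gain at activated loci, per-sample depth
  factors) and writes the ground truth next to the data.

## Worked example

Everything below runs in seconds from a fresh checkout; no downloads.

```python
from telocus import SimConfig, simulate_all, filter_peaks, peak_retention, \
    select_upregulated_tes
from telocus.enrichment import enrichment_analysis

bundle = simulate_all(SimConfig(seed=1))          # seeded synthetic dataset

ctrl = filter_peaks(bundle.control_peaks)          # >500 bp, reference chroms
treat = filter_peaks(bundle.treatment_peaks)
n, n_lost, frac = peak_retention(ctrl, treat)
print(f"control peaks: {n}   lost in treatment: {n_lost} ({100*frac:.1f}%)")

up = select_upregulated_tes(bundle.de_te)          # LFC > 0, padj < 0.05
print(f"upregulated TE loci: {len(up)}")
for r in enrichment_analysis(up, bundle.catalog, group_by="subfamily",
                             R=50_000, seed=1):
    if r.observed > r.expected_mean and r.p_two_sided < 0.01:
        print(f"{r.group}: observed {r.observed} vs expected "
              f"{r.expected_mean:.1f} +/- {r.expected_sd:.1f}, "
              f"p = {r.p_two_sided:.2e}")
```

Output:

```
control peaks: 652   lost in treatment: 556 (85.3%)
upregulated TE loci: 54
L1HS: observed 19 vs expected 4.0 +/- 1.9, p = 4.00e-05
L1PA2: observed 15 vs expected 4.0 +/- 1.9, p = 4.00e-05
L1PA3: observed 20 vs expected 4.0 +/- 1.9, p = 4.00e-05
```

Reading: the generator deleted 85% of control peaks at random, and the
retention estimate recovers that (85.3%). All 54 loci selected by the DE
thresholds are young full-length L1s, so the three young subfamilies are the
only groups whose observed count beats the resampled expectation — at
R = 50 000 the smallest attainable two-sided p is 2/(R+1) ≈ 4·10⁻⁵, which is
what fully separated groups report.

The same stages are available from the shell
(`telocus simulate|peaks|enrich|expr|meth|run`); `telocus run
--config run.yaml` executes the whole flow and writes `report.json` plus TSV
tables (exit codes: 2 config error, 3 stage failure).

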