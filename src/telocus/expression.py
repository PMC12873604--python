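"""Stranded L1 expression: normalization, DE selections, group comparisons.

Raw per-locus counts are depth-normalized with gene-derived median-of-ratios
size factors (the reference per gene is its cross-sample geometric mean, a
sample's factor the median ratio to that reference over all-positive genes).
Differential-expression summaries (baseMean / log2FoldChange / padj) are
consumed, not computed, and drive the selection rules: activated TE loci are
LFC > 0 with padj < 0.05, DE genes |LFC| > 1 with padj < 0.05, detectable
loci baseMean >= 1. Sense and antisense count strata are summarized per
condition, and groups of per-locus values are compared with the
Mann-Whitney U test (each locus an independent replicate).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Gene, TEElement

log = logging.getLogger(__name__)

DE_COLUMNS = ["locus_id", "baseMean", "log2FoldChange", "pvalue", "padj"]


@dataclass
class StrandedCountMatrix:
    locus_ids: list[str]
    sample_ids: list[str]
    sense_counts: np.ndarray      # loci x samples
    antisense_counts: np.ndarray  # loci x samples

    def __post_init__(self) -> None:
        self.sense_counts = np.asarray(self.sense_counts)
        self.antisense_counts = np.asarray(self.antisense_counts)
        shape = (len(self.locus_ids), len(self.sample_ids))
        if self.sense_counts.shape != shape or self.antisense_counts.shape != shape:
            raise ValueError("count grids must be loci x samples")
        for grid in (self.sense_counts, self.antisense_counts):
            if (grid < 0).any():
                raise ValueError("counts must be nonnegative")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        s = pd.DataFrame(self.sense_counts, index=self.locus_ids, columns=self.sample_ids)
        a = pd.DataFrame(self.antisense_counts, index=self.locus_ids, columns=self.sample_ids)
        return s, a


@dataclass
class SizeFactorSet:
    factors: dict[str, float]
    n_genes_used: int

    def __post_init__(self) -> None:
        for s, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"size factor for {s!r} must be positive, got {f}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors)


@dataclass
class MeanPlotPoint:
    locus_id: str
    mean_log2_control: float
    mean_log2_treatment: float
    significant: bool


def read_de_table(path_or_buf) -> pd.DataFrame:
    de = pd.read_csv(path_or_buf, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    return de


# -- normalization ----------------------------------------------------------

def size_factors_median_of_ratios(gene_counts: pd.DataFrame) -> SizeFactorSet:
    """Median-of-ratios size factors from a gene x sample count matrix.

    reference_i = geometric mean of gene i across samples, over genes with
    all counts > 0; factor_j = median_i(count_ij / reference_i). No further
    rescaling is applied.
    """
    counts = gene_counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has strictly positive counts in all samples")
    logc = np.log(counts[positive])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ratios, axis=0))
    return SizeFactorSet(
        {s: float(f) for s, f in zip(gene_counts.columns, factors)},
        n_genes_used=int(positive.sum()),
    )


def normalize_counts(counts: pd.DataFrame, factors: SizeFactorSet) -> pd.DataFrame:
    missing = [s for s in counts.columns if s not in factors.factors]
    if missing:
        raise KeyError(f"no size factor for samples: {missing}")
    return counts / pd.Series(factors.factors)[counts.columns]


# -- DE-table selections ----------------------------------------------------

def select_upregulated_tes(de: pd.DataFrame, lfc_min: float = 0.0,
                           padj_max: float = 0.05) -> set[str]:
    """Loci with LFC strictly > lfc_min and padj strictly < padj_max."""
    m = (de["log2FoldChange"] > lfc_min) & de["padj"].notna() & (de["padj"] < padj_max)
    return set(de.loc[m, "locus_id"])


def select_de_genes(de: pd.DataFrame, abs_lfc_min: float = 1.0,
                    padj_max: float = 0.05) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at |LFC| strictly > abs_lfc_min, padj < padj_max."""
    sig = de["padj"].notna() & (de["padj"] < padj_max)
    up = set(de.loc[sig & (de["log2FoldChange"] > abs_lfc_min), "locus_id"])
    down = set(de.loc[sig & (de["log2FoldChange"] < -abs_lfc_min), "locus_id"])
    return up, down


def select_detectable(de: pd.DataFrame, base_mean_min: float = 1.0) -> set[str]:
    """Loci with baseMean >= base_mean_min (inclusive)."""
    return set(de.loc[de["baseMean"] >= base_mean_min, "locus_id"])


def mean_plot_values(normalized: pd.DataFrame, groups: dict[str, str],
                     de: pd.DataFrame, lfc_min: float = 0.0,
                     padj_max: float = 0.05,
                     pseudocount: float = 0.5) -> list[MeanPlotPoint]:
    """Per-locus log2(mean normalized count + 0.5) per condition + DE flag."""
    conditions = sorted(set(groups.values()))
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    control, treatment = conditions[0], conditions[1]
    if "control" in conditions:  # put control first regardless of sort order
        control = "control"
        treatment = next(c for c in conditions if c != "control")
    cols_c = [s for s in normalized.columns if groups.get(s) == control]
    cols_t = [s for s in normalized.columns if groups.get(s) == treatment]
    sig = select_upregulated_tes(de, lfc_min, padj_max)
    in_de = set(de["locus_id"])
    points = []
    n_missing = 0
    for locus in normalized.index:
        if locus not in in_de:
            n_missing += 1
        points.append(MeanPlotPoint(
            locus_id=locus,
            mean_log2_control=float(np.log2(normalized.loc[locus, cols_c].mean() + pseudocount)),
            mean_log2_treatment=float(np.log2(normalized.loc[locus, cols_t].mean() + pseudocount)),
            significant=locus in sig,
        ))
    if n_missing:
        log.warning("%d loci missing from the DE table; flagged not significant",
                    n_missing)
    return points


# -- strand-aware summaries -------------------------------------------------

def sense_antisense_summary(counts: StrandedCountMatrix, factors: SizeFactorSet,
                            groups: dict[str, str],
                            loci: set[str] | None = None) -> pd.DataFrame:
    """Normalized per-condition mean counts per locus for both strands.

    Returns a locus-indexed frame with columns sense_<cond>/antisense_<cond>.
    """
    sense, antisense = counts.to_frames()
    if loci is not None:
        unknown = loci - set(counts.locus_ids)
        if unknown:
            raise KeyError(f"unknown loci: {sorted(unknown)[:5]}")
        sense = sense.loc[sorted(loci)]
        antisense = antisense.loc[sorted(loci)]
    sense_n = normalize_counts(sense, factors)
    anti_n = normalize_counts(antisense, factors)
    out = {}
    for cond in sorted(set(groups.values())):
        cols = [s for s in sense.columns if groups.get(s) == cond]
        out[f"sense_{cond}"] = sense_n[cols].mean(axis=1)
        out[f"antisense_{cond}"] = anti_n[cols].mean(axis=1)
    return pd.DataFrame(out)


# -- rank tests -------------------------------------------------------------

def mann_whitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Mann-Whitney U (U of x over y) with a two-sided p-value.

    Exact null when both samples are small (max n <= ``exact_max_n``) and
    tie-free; otherwise the normal approximation with continuity and tie
    correction. Each observation is an independent replicate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (tie_free and max(len(x), len(y)) <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def percent_of(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    value = 100.0 * numerator / denominator
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


# -- proximity analysis -----------------------------------------------------

def genes_near_elements(genes: list[Gene], elements: list[TEElement],
                        max_distance_bp: int = 50_000) -> set[str]:
    """Genes whose interval lies within ``max_distance_bp`` of any element
    (distance 0 for overlap)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in elements:
        by_chrom.setdefault(e.interval.chrom, []).append(
            (e.interval.start, e.interval.end))
    proximal = set()
    for g in genes:
        for s, e in by_chrom.get(g.interval.chrom, ()):
            gap = max(s - g.interval.end, g.interval.start - e, 0)
            if gap <= max_distance_bp:
                proximal.add(g.gene_id)
                break
    return proximal


def compare_lfc(proximal: set[str], distal: set[str],
                de: pd.DataFrame) -> tuple[float, float]:
    """Mann-Whitney comparison of gene LFC distributions, proximal vs distal."""
    lfc = de.set_index("locus_id")["log2FoldChange"]
    x = lfc.reindex(sorted(proximal)).dropna().to_numpy()
    y = lfc.reindex(sorted(distal)).dropna().to_numpy()
    return mann_whitney_u(x, y)
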