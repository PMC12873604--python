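"""Promoter 5mC/5hmC aggregation, composite profiles, paired comparisons.

Per-CpG modification calls (bedMethyl-style rows carrying coverage and
modified-call counts for the 5mC "m" or 5hmC "h" channel) are aggregated
into coverage-weighted promoter-window fractions, averaged into composite
profiles on a relative 5'->3' coordinate (with a seeded cap of 200 elements
per profile), and compared between conditions per element with the Wilcoxon
signed-rank test.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicInterval, TEElement

CHANNELS = {"m": "5mC", "h": "5hmC"}
_CHANNEL_CODES = {v: k for k, v in CHANNELS.items()}

SITE_COLUMNS = ["chrom", "pos", "strand", "channel", "n_valid", "n_mod", "sample_id"]

DEFAULT_MIN_COVERAGE = 4
DEFAULT_MAX_ELEMENTS = 200


@dataclass
class WindowSummary:
    region_id: str
    sample_id: str
    channel: str
    fraction: float | None  # None when undefined (too few qualifying sites)
    n_sites: int
    total_coverage: int

    @property
    def defined(self) -> bool:
        return self.fraction is not None


@dataclass
class CompositeProfile:
    channel: str
    bins: np.ndarray                      # relative bin midpoints in [0, 1]
    mean_fraction: dict[str, np.ndarray]  # condition -> per-bin mean
    n_per_bin: dict[str, np.ndarray]      # condition -> per-bin site count
    seed: int
    n_elements_used: int


@dataclass
class PairedComparison:
    element_ids: list[str]
    control_fractions: np.ndarray
    treatment_fractions: np.ndarray
    W_statistic: float
    p_two_sided: float
    n_pairs_used: int


# -- bedMethyl I/O ----------------------------------------------------------

def read_bedmethyl(lines: Iterable[str], channel: str,
                   sample_id: str = "") -> pd.DataFrame:
    """Read bedMethyl-dialect rows for one channel into a site-call frame.

    Columns: chrom, start, end, mod_code (m|h), coverage, strand, n_mod.
    Zero-coverage rows are dropped; n_mod > coverage is a hard error.
    """
    if channel not in _CHANNEL_CODES:
        raise ValueError(f"channel must be one of {sorted(_CHANNEL_CODES)}")
    code = _CHANNEL_CODES[channel]
    rows = []
    n_dropped = 0
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        chrom, start, _end, mod_code, coverage, strand, n_mod = line.split("\t")[:7]
        coverage, n_mod = int(coverage), int(n_mod)
        if n_mod > coverage:
            raise ValueError(f"line {ln}: n_mod {n_mod} exceeds coverage {coverage}")
        if mod_code != code:
            continue
        if coverage == 0:
            n_dropped += 1
            continue
        rows.append((chrom, int(start), strand, channel, coverage, n_mod, sample_id))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df.attrs["n_dropped_zero_coverage"] = n_dropped
    return df


def write_bedmethyl(calls: pd.DataFrame, handle) -> None:
    for row in calls.itertuples(index=False):
        code = _CHANNEL_CODES[row.channel]
        handle.write(
            f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{code}\t"
            f"{row.n_valid}\t{row.strand}\t{row.n_mod}\n"
        )


# -- window aggregation -----------------------------------------------------

def window_methylation(calls: pd.DataFrame, window: GenomicInterval,
                       region_id: str = "", sample_id: str = "",
                       channel: str | None = None,
                       min_coverage: int = DEFAULT_MIN_COVERAGE,
                       min_sites: int = 1) -> WindowSummary:
    """Coverage-weighted modification fraction over a window.

    Sites inside the window with coverage >= ``min_coverage`` contribute;
    fraction = sum(n_mod) / sum(n_valid). Fewer than ``min_sites``
    qualifying sites leaves the summary undefined.
    """
    sel = (
        (calls["chrom"] == window.chrom)
        & (calls["pos"] >= window.start)
        & (calls["pos"] < window.end)
        & (calls["n_valid"] >= min_coverage)
    )
    if channel is not None:
        sel &= calls["channel"] == channel
    sub = calls.loc[sel]
    n_sites = len(sub)
    total = int(sub["n_valid"].sum())
    if n_sites < min_sites or total == 0:
        return WindowSummary(region_id, sample_id, channel or "", None, n_sites, total)
    frac = float(sub["n_mod"].sum() / total)
    return WindowSummary(region_id, sample_id, channel or "", frac, n_sites, total)


def composite_profile(calls_by_condition: dict[str, pd.DataFrame],
                      elements: Sequence[TEElement], channel: str,
                      n_bins: int = 50,
                      max_elements: int | None = DEFAULT_MAX_ELEMENTS,
                      seed: int = 0,
                      min_coverage: int = DEFAULT_MIN_COVERAGE) -> CompositeProfile:
    """Length-scaled average modification profile across elements.

    Site positions map to a relative 5'->3' coordinate in [0, 1) per element
    ((pos - start)/length on +, (end - 1 - pos)/length on -) and are binned;
    per bin the coverage-weighted mean fraction is reported per condition.
    More than ``max_elements`` elements triggers a seeded uniform subsample.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    elements = list(elements)
    rng = np.random.default_rng(seed)
    if max_elements is not None and len(elements) > max_elements:
        idx = rng.choice(len(elements), size=max_elements, replace=False)
        elements = [elements[i] for i in sorted(idx)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    mean_fraction: dict[str, np.ndarray] = {}
    n_per_bin: dict[str, np.ndarray] = {}
    for cond, calls in calls_by_condition.items():
        mod = np.zeros(n_bins)
        cov = np.zeros(n_bins)
        n_sites = np.zeros(n_bins, dtype=int)
        good = calls.loc[(calls["channel"] == channel)
                         & (calls["n_valid"] >= min_coverage)]
        for e in elements:
            iv = e.interval
            if iv.strand == ".":
                raise ValueError(f"element {e.locus_id}: strand required")
            sub = good.loc[(good["chrom"] == iv.chrom)
                           & (good["pos"] >= iv.start) & (good["pos"] < iv.end)]
            if sub.empty:
                continue
            pos = sub["pos"].to_numpy()
            if iv.strand == "+":
                rel = (pos - iv.start) / len(iv)
            else:
                rel = (iv.end - 1 - pos) / len(iv)
            which = np.minimum((rel * n_bins).astype(int), n_bins - 1)
            np.add.at(mod, which, sub["n_mod"].to_numpy())
            np.add.at(cov, which, sub["n_valid"].to_numpy())
            np.add.at(n_sites, which, 1)
        with np.errstate(invalid="ignore"):
            mean_fraction[cond] = np.where(cov > 0, mod / np.maximum(cov, 1), np.nan)
        n_per_bin[cond] = n_sites
    return CompositeProfile(channel, mids, mean_fraction, n_per_bin,
                            seed, len(elements))


# -- paired tests -----------------------------------------------------------

def _wilcoxon_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank test by enumerating all 2^n sign patterns.

    Uses midranks of |d|, so remains exact under tied magnitudes.
    """
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = float(sum(r for r, s in zip(ranks, signs) if s))
        if min(wp, total - wp) <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2 ** n


def _wilcoxon_normal(d: np.ndarray) -> tuple[float, float]:
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2
    w = min(w_plus, total - w_plus)
    mean = n * (n + 1) / 4
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts ** 3 - tie_counts).sum() / 48
    if var <= 0:
        return w, 1.0
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction toward the null
    return w, float(min(1.0, 2 * stats.norm.cdf(z)))


def wilcoxon_signed_rank(control, treatment,
                         element_ids: Sequence[str] | None = None,
                         exact_max_n: int = 12) -> PairedComparison:
    """Paired Wilcoxon signed-rank test, W = min(W+, W-), two-sided.

    Zero differences are dropped; exact enumeration of sign patterns for
    n <= ``exact_max_n``, normal approximation with continuity and tie
    correction above.
    """
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if control.shape != treatment.shape:
        raise ValueError("paired samples must align")
    if element_ids is None:
        element_ids = [f"pair_{i}" for i in range(len(control))]
    d = treatment - control
    nonzero = d != 0
    d_used = d[nonzero]
    if len(d_used) == 0:
        raise ValueError("all paired differences are zero")
    if len(d_used) <= exact_max_n:
        w, p = _wilcoxon_exact(d_used)
    else:
        w, p = _wilcoxon_normal(d_used)
    return PairedComparison(list(element_ids), control, treatment,
                            W_statistic=w, p_two_sided=p,
                            n_pairs_used=int(nonzero.sum()))


def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi)}


def compare_conditions(summaries: Sequence[WindowSummary],
                       groups: dict[str, str], element_set: set[str],
                       channel: str):
    """Pair per-element condition means and test the condition difference.

    Window summaries (per element x sample x channel) are averaged within
    condition per element; elements undefined in either condition are
    dropped (count reported). Returns (PairedComparison, stats dict) where
    stats carries per-condition box-plot summaries, the median paired
    difference and the number of dropped elements.
    """
    conds = sorted(set(groups.values()))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    control = "control" if "control" in conds else conds[0]
    treatment = next(c for c in conds if c != control)
    per_elem: dict[str, dict[str, list[float]]] = {}
    for s in summaries:
        if s.channel != channel or not s.defined:
            continue
        if s.region_id not in element_set:
            continue
        cond = groups.get(s.sample_id)
        if cond is None:
            continue
        per_elem.setdefault(s.region_id, {}).setdefault(cond, []).append(s.fraction)
    ids, c_vals, t_vals = [], [], []
    n_dropped = 0
    for rid in sorted(element_set):
        means = per_elem.get(rid, {})
        if control in means and treatment in means:
            ids.append(rid)
            c_vals.append(float(np.mean(means[control])))
            t_vals.append(float(np.mean(means[treatment])))
        else:
            n_dropped += 1
    if not ids:
        raise ValueError("no element has defined summaries in both conditions")
    if all(c == t for c, t in zip(c_vals, t_vals)):
        # identical conditions carry no paired evidence
        comparison = PairedComparison(ids, np.array(c_vals), np.array(t_vals),
                                      W_statistic=0.0, p_two_sided=1.0,
                                      n_pairs_used=0)
    else:
        comparison = wilcoxon_signed_rank(c_vals, t_vals, element_ids=ids)
    c_arr, t_arr = np.array(c_vals), np.array(t_vals)
    stats_out = {
        "control": boxplot_stats(c_arr),
        "treatment": boxplot_stats(t_arr),
        "median_difference": float(np.median(t_arr - c_arr)),
        "n_elements": len(ids),
        "n_dropped": n_dropped,
    }
    return comparison, stats_out
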