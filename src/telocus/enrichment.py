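"""Observed-vs-expected TE family enrichment by annotation resampling.

The question: are transcriptionally activated TE loci concentrated in
particular families or subfamilies? The null keeps the number of activated
loci fixed and redraws that many loci uniformly, without replacement, from
the full annotation; each family's count under one draw is then compared to
the observed count. Over R replicates the score for a group counts draws
whose sampled count exceeds the observed one; the one-sided empirical
p-value is (score + 1) / (R + 1) (add-one so a zero score yields a positive,
conservative p) and the two-sided p doubles the smaller tail. A single
group's count under one draw is exactly hypergeometric, which provides an
analytic oracle for the Monte-Carlo tails.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .annotation import TECatalog

DEFAULT_RESAMPLES = 50_000


@dataclass
class FamilyCountVector:
    group_by: str  # "class" | "subfamily"
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.group_by not in {"class", "subfamily"}:
            raise ValueError(f"group_by must be class or subfamily, got {self.group_by!r}")
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for group {g!r}")

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class Replicates:
    """R resampled family-count vectors as a dense R x G grid."""

    group_by: str
    groups: list[str]
    counts: np.ndarray  # R x G, row sums all equal N
    N: int
    seed: int

    def __iter__(self):
        for row in self.counts:
            yield FamilyCountVector(self.group_by, dict(zip(self.groups, map(int, row))))


@dataclass
class EnrichmentResult:
    group: str
    observed: int
    expected_mean: float
    expected_sd: float
    score: int  # replicates where sampled count > observed
    n_resamples: int
    p_one: float
    p_two_sided: float
    seed: int

    @property
    def direction(self) -> str:
        return "enriched" if self.observed > self.expected_mean else "depleted"


def _group_key(group_by: str):
    if group_by == "class":
        return lambda e: e.te_class
    return lambda e: e.subfamily


def catalog_group_sizes(catalog: TECatalog, group_by: str) -> dict[str, int]:
    key = _group_key(group_by)
    sizes: dict[str, int] = {}
    for e in catalog:
        g = key(e)
        sizes[g] = sizes.get(g, 0) + 1
    return dict(sorted(sizes.items()))


def observed_counts(upregulated_ids: Iterable[str], catalog: TECatalog,
                    group_by: str = "class") -> FamilyCountVector:
    """Count activated loci per group; groups present in the catalog but with
    zero observed loci are still reported."""
    key = _group_key(group_by)
    counts = {g: 0 for g in catalog_group_sizes(catalog, group_by)}
    known = catalog.ids()
    for locus_id in upregulated_ids:
        if locus_id not in known:
            raise KeyError(f"unknown locus id {locus_id!r}")
        counts[key(catalog.by_id(locus_id))] += 1
    return FamilyCountVector(group_by, counts)


def resample_expected(catalog: TECatalog, N: int, R: int, seed: int,
                      group_by: str = "class") -> Replicates:
    """Draw R null replicates of N loci without replacement from the catalog.

    Group counts of a uniform without-replacement draw follow the
    multivariate hypergeometric law over the catalog's group sizes, which is
    what is sampled here, one vector per replicate.
    """
    T = len(catalog)
    if not 1 <= N <= T:
        raise ValueError(f"N={N} out of range for catalog of {T} loci")
    if R < 1:
        raise ValueError("R must be >= 1")
    sizes = catalog_group_sizes(catalog, group_by)
    groups = list(sizes)
    rng = np.random.default_rng(seed)
    counts = rng.multivariate_hypergeometric(
        [sizes[g] for g in groups], N, size=R
    ).astype(np.int64)
    return Replicates(group_by, groups, counts, N, seed)


def empirical_test(observed: FamilyCountVector,
                   replicates: Replicates) -> list[EnrichmentResult]:
    """Per-group empirical two-sided test of observed vs resampled counts.

    score_g counts replicates whose sampled count strictly exceeds the
    observed one (sampled == observed falls on the non-exceeding side);
    p_one = (score+1)/(R+1), p_two = min(1, 2*min(p_one, 1-p_one)).
    """
    if observed.group_by != replicates.group_by:
        raise ValueError("observed and replicates use different groupings")
    if observed.total() != replicates.N:
        raise ValueError(
            f"observed total {observed.total()} != resample size {replicates.N}")
    R = replicates.counts.shape[0]
    results = []
    for gi, g in enumerate(replicates.groups):
        obs = observed.counts.get(g, 0)
        col = replicates.counts[:, gi]
        score = int((col > obs).sum())
        p_one = (score + 1) / (R + 1)
        p_two = min(1.0, 2.0 * min(p_one, 1.0 - p_one))
        results.append(EnrichmentResult(
            group=g, observed=obs,
            expected_mean=float(col.mean()),
            expected_sd=float(col.std(ddof=1)) if R > 1 else 0.0,
            score=score, n_resamples=R, p_one=p_one, p_two_sided=p_two,
            seed=replicates.seed,
        ))
    return results


def enrichment_analysis(upregulated_ids: Iterable[str], catalog: TECatalog,
                        group_by: str = "class", R: int = DEFAULT_RESAMPLES,
                        seed: int = 0) -> list[EnrichmentResult]:
    """Observed counts -> null resampling -> empirical test, in one call."""
    obs = observed_counts(upregulated_ids, catalog, group_by)
    reps = resample_expected(catalog, max(obs.total(), 1), R, seed, group_by)
    if obs.total() == 0:
        raise ValueError("no upregulated loci to test")
    return empirical_test(obs, reps)


def hypergeometric_oracle(T: int, K_g: int, N: int, observed: int) -> float:
    """Exact P(count > observed) for one group under a single null draw.

    The count of group g among N loci drawn without replacement from T is
    Hypergeometric(T, K_g, N); this is the analytic counterpart of a single
    replicate's score contribution, evaluated in log space by scipy.
    """
    if not 0 <= K_g <= T:
        raise ValueError(f"need 0 <= K_g <= T, got K_g={K_g}, T={T}")
    if not 0 <= N <= T:
        raise ValueError(f"need 0 <= N <= T, got N={N}, T={T}")
    if observed >= min(K_g, N):
        return 0.0
    if observed < 0:
        return 1.0
    return float(stats.hypergeom.sf(observed, T, K_g, N))


def results_to_rows(results: Sequence[EnrichmentResult]) -> list[dict]:
    return [
        {
            "group": r.group, "observed": r.observed,
            "expected_mean": r.expected_mean, "expected_sd": r.expected_sd,
            "score": r.score, "n_resamples": r.n_resamples,
            "p_one": r.p_one, "p_two_sided": r.p_two_sided,
        }
        for r in results
    ]
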