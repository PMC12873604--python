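"""Peak post-filtering, interval overlap, TE-class assignment and signal.

Peaks arrive as called intervals (SEACR-style BED); this module applies the
post-filter (longer than 500 bp, reference chromosomes only), assigns each
peak to the TE class of its best-overlapping element, measures condition-to-
condition peak retention, bins signal tracks into region x bin matrices
(reference-point or scale-regions, strand-aware) and clusters rows with a
seeded k-means.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import (
    REFERENCE_CHROMS,
    GenomicInterval,
    TECatalog,
)

DEFAULT_MIN_PEAK_BP = 500


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")


@dataclass
class PeakSet:
    condition: str
    replicate: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def read_peaks_bed(lines: Iterable[str], condition: str = "",
                   replicate: str = "") -> PeakSet:
    """Read a SEACR-style BED (>=3 columns; column 4 taken as score if numeric)."""
    peaks = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        score = 0.0
        if len(cols) >= 4:
            try:
                score = float(cols[3])
            except ValueError:
                if len(cols) >= 5:
                    try:
                        score = float(cols[4])
                    except ValueError:
                        score = 0.0
        peaks.append(Peak(GenomicInterval(cols[0], int(cols[1]), int(cols[2])),
                          max(score, 0.0)))
    return PeakSet(condition, replicate, peaks)


def write_peaks_bed(peaks: PeakSet, handle) -> None:
    for p in peaks:
        iv = p.interval
        handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.score:g}\n")


# -- filtering and overlap --------------------------------------------------

def filter_peaks(peaks: PeakSet, min_length_bp: int = DEFAULT_MIN_PEAK_BP,
                 reference_chroms=REFERENCE_CHROMS) -> PeakSet:
    """Keep peaks strictly longer than ``min_length_bp`` on reference chroms."""
    if min_length_bp < 0:
        raise ValueError("min_length_bp must be >= 0")
    kept = [p for p in peaks
            if len(p.interval) > min_length_bp
            and p.interval.chrom in reference_chroms]
    return PeakSet(peaks.condition, peaks.replicate, kept)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _check_sorted(intervals: Sequence[GenomicInterval], name: str) -> None:
    keys = [(iv.chrom, iv.start) for iv in intervals]
    if keys != sorted(keys):
        raise ValueError(f"{name} intervals are not sorted by (chrom, start)")


def intersect_sets(A: Sequence[GenomicInterval],
                   B: Sequence[GenomicInterval]) -> list[tuple[int, int, int]]:
    """All overlapping pairs between two sorted interval sets, by sweep line.

    Returns (a_index, b_index, overlap_bp) triples, each pair once, in
    order of the A sweep. Inputs must be sorted by (chrom, start).
    """
    _check_sorted(A, "A")
    _check_sorted(B, "B")
    out: list[tuple[int, int, int]] = []
    j0 = 0
    for i, a in enumerate(A):
        # advance the lower pointer past B intervals wholly before a's chrom
        while j0 < len(B) and (B[j0].chrom < a.chrom):
            j0 += 1
        j = j0
        while j < len(B) and B[j].chrom == a.chrom and B[j].start < a.end:
            ov = min(a.end, B[j].end) - max(a.start, B[j].start)
            if ov > 0:
                out.append((i, j, ov))
            j += 1
        # b intervals ending before every later a start can never match again;
        # conservatively advance j0 only past those fully left of a.start
        while j0 < len(B) and B[j0].chrom == a.chrom and B[j0].end <= a.start:
            j0 += 1
    return out


def assign_peak_classes(peaks: PeakSet, catalog: TECatalog):
    """Label each peak with the TE class of its best-overlapping element.

    Ties break toward larger overlap, then younger element, then leftmost.
    Peaks overlapping no element are "non-TE". Returns (labels, summary) where
    summary carries the TE/non-TE split and per-class fractions among TE peaks.
    """
    elems = sorted(catalog.elements,
                   key=lambda e: (e.interval.chrom, e.interval.start))
    pairs = intersect_sets(peaks.intervals(), [e.interval for e in elems])
    best: dict[int, tuple] = {}
    for i, j, ov in pairs:
        e = elems[j]
        key = (-ov, e.age_rank, e.interval.chrom, e.interval.start)
        if i not in best or key < best[i][0]:
            best[i] = (key, e.te_class)
    labels = [best[i][1] if i in best else "non-TE" for i in range(len(peaks))]
    n = len(labels)
    n_te = sum(1 for l in labels if l != "non-TE")
    per_class: dict[str, float] = {}
    if n_te:
        for l in labels:
            if l != "non-TE":
                per_class[l] = per_class.get(l, 0) + 1
        per_class = {k: v / n_te for k, v in sorted(per_class.items())}
    summary = {
        "n_peaks": n,
        "fraction_te": (n_te / n) if n else 0.0,
        "fraction_non_te": ((n - n_te) / n) if n else 0.0,
        "te_class_fractions": per_class,
    }
    return labels, summary


def peak_retention(control: PeakSet, treatment: PeakSet) -> tuple[int, int, float]:
    """Count control peaks lost in treatment (no >=1 bp overlap retained).

    Returns (n_control, n_lost, fraction_lost).
    """
    if len(control) == 0:
        raise ValueError("empty control peak set")
    pairs = intersect_sets(control.intervals(), treatment.intervals())
    retained = {i for i, _, _ in pairs}
    n_control = len(control)
    n_lost = n_control - len(retained)
    return n_control, n_lost, n_lost / n_control


# -- binned signal ----------------------------------------------------------

class SignalTrack:
    """Per-chromosome bedGraph segments with numpy-backed lookup."""

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._segs = dict(segments)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        acc: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in rows:
            acc.setdefault(chrom, []).append((int(s), int(e), float(v)))
        segs = {}
        for chrom, items in acc.items():
            items.sort()
            segs[chrom] = (
                np.array([r[0] for r in items], dtype=np.int64),
                np.array([r[1] for r in items], dtype=np.int64),
                np.array([r[2] for r in items], dtype=float),
            )
        return cls(segs)

    @classmethod
    def from_bedgraph(cls, lines: Iterable[str]) -> "SignalTrack":
        acc: dict[str, list[tuple[int, int, float]]] = {}
        for line in lines:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            acc.setdefault(chrom, []).append((int(s), int(e), float(v)))
        segs = {}
        for chrom, rows in acc.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            segs[chrom] = (starts, ends, vals)
        return cls(segs)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Average value over [start, end); positions without data count as 0."""
        if end <= start:
            return 0.0
        if chrom not in self._segs:
            return 0.0
        starts, ends, vals = self._segs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = (np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)).clip(min=0)
        return float((ov * vals[lo:hi]).sum() / (end - start))


@dataclass
class SignalMatrix:
    region_ids: list[str]
    mode: str  # "reference-point" | "scale-regions"
    bin_size_bp: int
    upstream_bp: int
    downstream_bp: int
    body_bins: int
    values: np.ndarray  # regions x bins

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.region_ids):
            raise ValueError("values grid must be regions x bins")
        expected = self.upstream_bp // self.bin_size_bp
        if self.mode == "scale-regions":
            expected += self.body_bins + self.downstream_bp // self.bin_size_bp
        else:
            expected += self.downstream_bp // self.bin_size_bp
        if self.values.shape[1] != expected:
            raise ValueError(
                f"bin count {self.values.shape[1]} inconsistent with mode "
                f"parameters (expected {expected})")

    def n_flank_bins(self) -> int:
        return self.upstream_bp // self.bin_size_bp

    def to_tsv(self, handle) -> None:
        header = {
            "mode": self.mode, "bin_size_bp": self.bin_size_bp,
            "upstream_bp": self.upstream_bp, "downstream_bp": self.downstream_bp,
            "body_bins": self.body_bins,
        }
        handle.write("#" + json.dumps(header) + "\n")
        for rid, row in zip(self.region_ids, self.values):
            handle.write(rid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, lines: Iterable[str]) -> "SignalMatrix":
        it = iter(lines)
        header = json.loads(next(it).lstrip("#"))
        ids, rows = [], []
        for line in it:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(ids, header["mode"], header["bin_size_bp"],
                   header["upstream_bp"], header["downstream_bp"],
                   header["body_bins"], np.array(rows, dtype=float))


def compute_signal_matrix(track: SignalTrack,
                          regions: Sequence[GenomicInterval],
                          region_ids: Sequence[str] | None = None,
                          mode: str = "reference-point",
                          bin_size_bp: int = 100,
                          upstream_bp: int = 2000,
                          downstream_bp: int = 2000,
                          body_bins: int = 20) -> SignalMatrix:
    """Bin a coverage track over regions, strand-aware (bin 0 is 5'-most).

    reference-point mode anchors at each region's 5' end with
    upstream/downstream flanks; scale-regions mode adds a body linearly
    rescaled to ``body_bins``. Positions without track data contribute 0.
    """
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    if mode not in {"reference-point", "scale-regions"}:
        raise ValueError(f"unknown mode {mode!r}")
    if region_ids is None:
        region_ids = [f"region_{i}" for i in range(len(regions))]
    n_up = upstream_bp // bin_size_bp
    n_down = downstream_bp // bin_size_bp
    rows = []
    for iv in regions:
        minus = iv.strand == "-"
        anchor5 = iv.end if minus else iv.start
        bins: list[tuple[int, int]] = []
        if mode == "reference-point":
            # genomic offsets relative to the 5' anchor, walking 5'->3'
            for b in range(-n_up, n_down):
                off0, off1 = b * bin_size_bp, (b + 1) * bin_size_bp
                if minus:
                    bins.append((anchor5 - off1, anchor5 - off0))
                else:
                    bins.append((anchor5 + off0, anchor5 + off1))
        else:
            anchor3 = iv.start if minus else iv.end
            for b in range(-n_up, 0):
                off0, off1 = b * bin_size_bp, (b + 1) * bin_size_bp
                if minus:
                    bins.append((anchor5 - off1, anchor5 - off0))
                else:
                    bins.append((anchor5 + off0, anchor5 + off1))
            body_edges = np.linspace(iv.start, iv.end, body_bins + 1)
            body = [(int(body_edges[i]), int(body_edges[i + 1]))
                    for i in range(body_bins)]
            if minus:
                body = body[::-1]
            bins.extend(body)
            for b in range(0, n_down):
                off0, off1 = b * bin_size_bp, (b + 1) * bin_size_bp
                if minus:
                    bins.append((anchor3 - off1, anchor3 - off0))
                else:
                    bins.append((anchor3 + off0, anchor3 + off1))
        row = [track.mean_over(iv.chrom, max(s, 0), max(e, 0)) for s, e in bins]
        rows.append(row)
    values = np.array(rows, dtype=float) if rows else np.zeros((0, n_up + n_down))
    return SignalMatrix(list(region_ids), mode, bin_size_bp, upstream_bp,
                        downstream_bp, body_bins if mode == "scale-regions" else 0,
                        values)


def rpkm_normalize(bin_counts, total_mapped_reads: float, bin_size_bp: int):
    """Reads per kilobase of bin per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    counts = np.asarray(bin_counts, dtype=float)
    return counts / ((bin_size_bp / 1000.0) * (total_mapped_reads / 1e6))


# -- clustering -------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: dict[str, int]
    centroids: np.ndarray
    k: int
    seed: int
    inertia: float = 0.0
    inertia_trace: list[float] = field(default_factory=list)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(1))
    return centers


def kmeans_rows(matrix: SignalMatrix, k: int, seed: int,
                n_init: int = 10, max_iter: int = 300) -> ClusterResult:
    """Seeded Lloyd's k-means with k-means++ starts over matrix rows.

    Deterministic for fixed (matrix, k, seed); keeps the inertia trajectory
    of the winning restart (non-increasing across Lloyd iterations).
    """
    X = matrix.values
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} regions")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_init):
        centers = _kmeanspp_init(X, k, rng)
        labels = None
        trace: list[float] = []
        for _ in range(max_iter):
            d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            new_labels = d.argmin(1)
            trace.append(float(d[np.arange(n), new_labels].sum()))
            if labels is not None and np.array_equal(labels, new_labels):
                break
            labels = new_labels
            for j in range(k):
                members = X[labels == j]
                if len(members):
                    centers[j] = members.mean(0)
        inertia = trace[-1]
        if best is None or inertia < best[0]:
            best = (inertia, labels.copy(), centers.copy(), trace)
    inertia, labels, centers, trace = best
    return ClusterResult(
        assignments={rid: int(l) for rid, l in zip(matrix.region_ids, labels)},
        centroids=centers, k=k, seed=seed, inertia=inertia, inertia_trace=trace,
    )


def promoter_peak_confidence(matrix: SignalMatrix,
                             background_quantile: float = 0.75,
                             fold_threshold: float = 5.0) -> dict[str, str]:
    """Tiered promoter-signal call per region: high / low / none.

    Thresholded stand-in for by-eye browser curation of promoter marks:
    "high" when the mean signal over the promoter-side bins reaches
    ``fold_threshold`` times the genome background (the given quantile of
    all matrix bins), "low" when above background but under the threshold,
    "none" otherwise.
    """
    if matrix.mode != "reference-point":
        raise ValueError("confidence calls need a reference-point matrix")
    background = float(np.quantile(matrix.values, background_quantile))
    n_up = matrix.upstream_bp // matrix.bin_size_bp
    promoter = matrix.values[:, n_up:]  # downstream of the 5' anchor
    out = {}
    floor = max(background, 1e-12)
    for rid, row in zip(matrix.region_ids, promoter):
        m = float(row.mean())
        if m >= fold_threshold * floor:
            out[rid] = "high"
        elif m > background:
            out[rid] = "low"
        else:
            out[rid] = "none"
    return out
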