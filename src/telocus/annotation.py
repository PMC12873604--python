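"""TE and gene catalogs: parsing, full-length classification, age ordering.

All internal coordinates are 0-based half-open (BED convention); the GTF
reader/writer converts at the boundary. A transposable-element catalog is the
substrate of every downstream analysis: each locus carries a class (L1, Alu,
ERV, SVA, other), a subfamily (L1HS, L1PA2, ...), an evolutionary age rank
(0 = youngest) and a full-length flag (strictly longer than a per-class
threshold, 6 kb for L1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Autosomes plus X and Y; alternative contigs and scaffolds are excluded
#: from peak analyses by default.
REFERENCE_CHROMS: frozenset[str] = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"}
)

#: Strictly-greater-than length thresholds (bp) for full-length status.
DEFAULT_FL_THRESHOLDS: dict[str, int] = {"L1": 6000}

#: Default promoter-window extent. The L1 5' UTR, which contains the
#: bidirectional internal promoter, is ~900 bp; 1 kb covers it.
DEFAULT_PROMOTER_BP = 1000

#: age rank assigned to subfamilies absent from the ordering table
UNRANKED_AGE_RANK = 10_000
_UNRANKED = UNRANKED_AGE_RANK


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TEElement:
    locus_id: str
    interval: GenomicInterval
    te_class: str
    subfamily: str
    age_rank: int = _UNRANKED
    full_length: bool = False

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand == ".":
            raise ValueError(f"gene {self.gene_id}: strand is mandatory")


@dataclass
class TECatalog:
    elements: list[TEElement]
    subfamily_to_class: dict[str, str] = field(default_factory=dict)
    age_order: list[str] = field(default_factory=list)
    reference_chroms: frozenset[str] = REFERENCE_CHROMS

    def __post_init__(self) -> None:
        ids = [e.locus_id for e in self.elements]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate locus_id {i!r} in catalog")
                seen.add(i)
        for e in self.elements:
            self.subfamily_to_class.setdefault(e.subfamily, e.te_class)
        if len(self.age_order) != len(set(self.age_order)):
            raise ValueError("age_order contains duplicates")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def by_id(self, locus_id: str) -> TEElement:
        if not hasattr(self, "_index"):
            self._index = {e.locus_id: e for e in self.elements}
        return self._index[locus_id]

    def ids(self) -> set[str]:
        return {e.locus_id for e in self.elements}

    def subset(self, predicate) -> "TECatalog":
        return TECatalog(
            [e for e in self.elements if predicate(e)],
            dict(self.subfamily_to_class),
            list(self.age_order),
            self.reference_chroms,
        )


# -- class vocabulary -------------------------------------------------------

_CLASS_VOCAB = ("L1", "Alu", "ERV", "SVA", "other")


def normalize_class(family_id: str, class_id: str = "") -> str:
    """Map RepeatMasker family/class labels onto {L1, Alu, ERV, SVA, other}."""
    fam = family_id.strip()
    if fam in _CLASS_VOCAB:
        return fam
    if fam.startswith("L1"):
        return "L1"
    if fam.startswith("Alu"):
        return "Alu"
    if fam.startswith("ERV") or class_id == "LTR":
        return "ERV"
    if fam.startswith("SVA") or class_id == "Retroposon":
        return "SVA"
    return "other"


def load_age_order() -> list[str]:
    """Packaged L1 subfamily chronology, youngest first (L1HS = rank 0)."""
    text = resources.files("telocus.data").joinpath("l1_age_order.tsv").read_text()
    pairs = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        subfamily, rank = line.split("\t")
        pairs.append((int(rank), subfamily))
    return [s for _, s in sorted(pairs)]


def age_rank_map(age_order: Sequence[str] | None = None) -> dict[str, int]:
    order = list(age_order) if age_order is not None else load_age_order()
    return {s: i for i, s in enumerate(order)}


# -- GTF / BED I/O ----------------------------------------------------------

def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        value = value.strip().strip('"')
        if not key or not value:
            raise ValueError(f"malformed attribute {part!r}")
        out[key] = value
    return out


def parse_te_gtf(lines: Iterable[str], age_order: Sequence[str] | None = None) -> TECatalog:
    """Parse a TEtranscripts-dialect GTF into a :class:`TECatalog`.

    Each record carries ``gene_id`` (subfamily), ``transcript_id`` (locus),
    ``family_id`` and ``class_id`` attributes with 1-based inclusive
    coordinates. Malformed records are skipped with a logged warning;
    duplicated transcript_ids are a hard error.
    """
    ranks = age_rank_map(age_order)
    elements: list[TEElement] = []
    seen: set[str] = set()
    sub2class: dict[str, str] = {}
    n_bad = n_total = 0
    for raw in lines:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        n_total += 1
        try:
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"expected 9 columns, got {len(cols)}")
            chrom, _, _, start1, end1, _, strand, _, attr = cols
            attrs = _parse_attributes(attr)
            locus_id = attrs["transcript_id"]
            subfamily = attrs["gene_id"]
            te_class = normalize_class(attrs.get("family_id", subfamily),
                                       attrs.get("class_id", ""))
            interval = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
        except (ValueError, KeyError, IndexError) as exc:
            n_bad += 1
            log.warning("skipping malformed GTF record: %s (%s)", line[:80], exc)
            continue
        if locus_id in seen:
            raise ValueError(f"duplicate transcript_id {locus_id!r}")
        seen.add(locus_id)
        sub2class.setdefault(subfamily, te_class)
        elements.append(
            TEElement(locus_id, interval, te_class, subfamily,
                      age_rank=ranks.get(subfamily, _UNRANKED))
        )
    if n_bad:
        log.warning("parsed %d/%d GTF records (%d malformed, skipped)",
                    len(elements), n_total, n_bad)
    order = list(age_order) if age_order is not None else load_age_order()
    return TECatalog(elements, sub2class, order)


def write_te_gtf(catalog: TECatalog, handle) -> None:
    """Serialize a catalog back to the TEtranscripts GTF dialect (1-based)."""
    for e in catalog:
        iv = e.interval
        attrs = (
            f'gene_id "{e.subfamily}"; transcript_id "{e.locus_id}"; '
            f'family_id "{e.te_class}"; class_id "{e.te_class}";'
        )
        handle.write(
            f"{iv.chrom}\ttelocus\texon\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}\n"
        )


def read_bed6(lines: Iterable[str]) -> list[GenomicInterval]:
    out = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        strand = cols[5] if len(cols) >= 6 else "."
        out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed6(intervals: Iterable[GenomicInterval], handle,
               names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    for i, iv in enumerate(intervals):
        name = names[i] if names else f"region_{i}"
        handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# -- operations -------------------------------------------------------------

def classify_full_length(catalog: TECatalog,
                         thresholds: Mapping[str, int] | None = None) -> TECatalog:
    """Flag elements strictly longer than their class threshold (L1: >6 kb)."""
    thresholds = dict(thresholds if thresholds is not None else DEFAULT_FL_THRESHOLDS)
    for t in thresholds.values():
        if t < 0:
            raise ValueError(f"negative full-length threshold: {t}")
    elements = [
        replace(e, full_length=(e.te_class in thresholds
                                and e.length > thresholds[e.te_class]))
        for e in catalog
    ]
    return TECatalog(elements, dict(catalog.subfamily_to_class),
                     list(catalog.age_order), catalog.reference_chroms)


def promoter_window(element: TEElement, length_bp: int = DEFAULT_PROMOTER_BP) -> GenomicInterval:
    """The 5'-most ``length_bp`` of an element, clipped to its bounds.

    For L1 this covers the internal bidirectional promoter in the 5' UTR.
    """
    if length_bp <= 0:
        raise ValueError("promoter length must be positive")
    iv = element.interval
    if iv.strand == ".":
        raise ValueError(f"element {element.locus_id}: promoter undefined "
                         "for strandless interval")
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start, min(iv.start + length_bp, iv.end), "+")
    return GenomicInterval(iv.chrom, max(iv.end - length_bp, iv.start), iv.end, "-")


def age_sort(elements: Sequence[TEElement]) -> list[TEElement]:
    """Sort youngest-first by age rank, ties broken by (chrom, start)."""
    return sorted(elements,
                  key=lambda e: (e.age_rank, e.interval.chrom, e.interval.start))


def filter_reference_chroms(intervals: Sequence, reference_chroms=REFERENCE_CHROMS):
    """Keep items on reference chromosomes, preserving order.

    Accepts bare intervals or any objects with an ``interval`` attribute.
    """
    if not reference_chroms:
        raise ValueError("reference_chroms must be nonempty")

    def chrom_of(x):
        return x.interval.chrom if hasattr(x, "interval") else x.chrom

    return [x for x in intervals if chrom_of(x) in reference_chroms]
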