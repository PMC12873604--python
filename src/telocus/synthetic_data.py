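"""Seeded generator of a reduced-scale TE-regulation dataset with ground truth.

The generator emulates, on toy chromosomes, the statistical structure the
analysis assumes: an hg38-like TE composition with age-ordered L1 subfamilies
and full-length (>6 kb) young L1 loci; repressive-mark peaks covering young
FL-L1s in control with a configurable ~85% loss in treatment plus ectopic
chromosome-end blocks; negative-binomial stranded counts with sense-biased
activation planted in a fraction of young FL-L1s and per-sample depth
factors; an emulated differential-expression table consistent with the
planted truth; and per-CpG 5mC/5hmC calls with promoter methylation loss and
hydroxymethylation gain at activated loci. Identical config + seed gives
byte-identical fixture files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    UNRANKED_AGE_RANK,
    GenomicInterval,
    Gene,
    TECatalog,
    TEElement,
    classify_full_length,
    write_bed6,
    write_te_gtf,
)
from .expression import StrandedCountMatrix
from .methylation import SITE_COLUMNS, write_bedmethyl
from .peaks import Peak, PeakSet, write_peaks_bed

YOUNG_MAX_AGE_RANK = 2  # L1HS, L1PA2, L1PA3


@dataclass(frozen=True)
class FamilySpec:
    count: int
    length_range: tuple[int, int]
    te_class: str
    age_rank: int


def _default_composition() -> dict[str, FamilySpec]:
    # truncated-copy composition, roughly L1-heavy like hg38 at toy scale
    return {
        "L1HS": FamilySpec(80, (800, 3000), "L1", 0),
        "L1PA2": FamilySpec(80, (800, 3000), "L1", 1),
        "L1PA3": FamilySpec(80, (800, 3000), "L1", 2),
        "L1PA4": FamilySpec(120, (600, 2500), "L1", 3),
        "L1PA7": FamilySpec(140, (500, 2000), "L1", 6),
        "AluY": FamilySpec(260, (250, 350), "Alu", UNRANKED_AGE_RANK),
        "AluSx": FamilySpec(260, (250, 350), "Alu", UNRANKED_AGE_RANK),
        "HERVK-int": FamilySpec(150, (400, 2000), "ERV", UNRANKED_AGE_RANK),
        "ERVL-E-int": FamilySpec(150, (400, 2000), "ERV", UNRANKED_AGE_RANK),
        "SVA_A": FamilySpec(60, (800, 1600), "SVA", UNRANKED_AGE_RANK),
        "SVA_B": FamilySpec(60, (800, 1600), "SVA", UNRANKED_AGE_RANK),
        "MIR": FamilySpec(240, (100, 250), "other", UNRANKED_AGE_RANK),
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 3
    chrom_length_bp: int = 10_000_000
    family_composition: dict[str, FamilySpec] = field(default_factory=_default_composition)
    n_full_length_per_L1_subfamily: dict[str, int] = field(
        default_factory=lambda: {"L1HS": 60, "L1PA2": 60, "L1PA3": 60, "L1PA4": 40})
    fl_length_range: tuple[int, int] = (6001, 7000)
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (1000, 5000)
    sample_design: dict[str, int] = field(
        default_factory=lambda: {"control": 2, "treatment": 2})
    true_depth_factors: dict[str, float] = field(default_factory=lambda: {
        "control_rep1": 1.0, "control_rep2": 0.8,
        "treatment_rep1": 1.2, "treatment_rep2": 1.0})
    nb_dispersion: float = 0.1
    gene_log_mean: float = 4.0
    gene_log_sd: float = 1.0
    frac_de_genes: float = 0.1
    te_log_mean: float = 1.5
    te_log_sd: float = 1.0
    frac_activated_young_L1: float = 0.3
    activation_lfc: float = 3.0
    sense_bias: float = 0.8
    # peaks
    peak_loss_fraction: float = 0.85
    peak_jitter_bp: tuple[int, int] = (200, 1000)
    n_background_peaks: int = 500
    background_peak_length: tuple[int, int] = (600, 3000)
    ectopic_block_spec: tuple[int, int] = (2, 100_000)  # blocks per chrom, bp
    # promoter signal (activating mark at 5' ends)
    signal_bin_bp: int = 100
    signal_noise_range: tuple[float, float] = (0.1, 0.2)
    promoter_high_amp: tuple[float, float] = (1.5, 3.0)
    promoter_low_amp: tuple[float, float] = (0.3, 0.45)
    frac_low_tier: float = 0.15
    promoter_signal_bp: int = 1000
    peak_signal_value: float = 10.0
    # methylation
    meth_control_beta: tuple[float, float] = (17.0, 3.0)
    meth_activated_treatment_beta: tuple[float, float] = (4.0, 6.0)
    hmc_control_mean: float = 0.02
    hmc_activated_mean: float = 0.10
    hmc_concentration: float = 100.0
    cpg_spacing_bp: int = 150
    coverage_lambda: float = 15.0

    def validate(self) -> None:
        for name, p in [("frac_activated_young_L1", self.frac_activated_young_L1),
                        ("peak_loss_fraction", self.peak_loss_fraction),
                        ("frac_de_genes", self.frac_de_genes),
                        ("frac_low_tier", self.frac_low_tier)]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.5 < self.sense_bias <= 1:
            raise ValueError("sense_bias must be in (0.5, 1]")
        if self.n_chroms < 1 or self.chrom_length_bp < 1 or self.n_genes < 0:
            raise ValueError("counts must be positive")

    def samples(self) -> dict[str, str]:
        out = {}
        for cond, n in self.sample_design.items():
            for r in range(1, n + 1):
                out[f"{cond}_rep{r}"] = cond
        return out

    def chrom_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chroms + 1)]

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimBundle:
    config: SimConfig
    catalog: TECatalog
    genes: list[Gene]
    control_peaks: PeakSet
    treatment_peaks: PeakSet
    peak_truth: pd.DataFrame
    te_counts: StrandedCountMatrix
    gene_counts: pd.DataFrame
    de_te: pd.DataFrame
    de_genes: pd.DataFrame
    activated_ids: list[str]
    promoter_tiers: dict[str, str]
    signal_tracks: dict[str, list[tuple[str, int, int, float]]]
    meth_calls: pd.DataFrame  # all samples, both channels
    meth_truth: pd.DataFrame


def young_fl_l1_ids(catalog: TECatalog) -> list[str]:
    return [e.locus_id for e in catalog
            if e.te_class == "L1" and e.full_length
            and e.age_rank <= YOUNG_MAX_AGE_RANK]


# -- catalog ----------------------------------------------------------------

def simulate_catalog(config: SimConfig,
                     rng: np.random.Generator) -> tuple[TECatalog, list[Gene]]:
    """Place non-overlapping TE loci and genes uniformly on toy chromosomes."""
    config.validate()
    items: list[tuple[str, str, str, int, int]] = []  # kind, id, subfamily, length, age
    counter: dict[str, int] = {}

    def new_id(subfamily: str) -> str:
        counter[subfamily] = counter.get(subfamily, 0) + 1
        return f"{subfamily}_{counter[subfamily]}"

    for sub, spec in config.family_composition.items():
        for _ in range(spec.count):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            items.append(("te", new_id(sub), sub, length, spec.age_rank))
    for sub, n_fl in config.n_full_length_per_L1_subfamily.items():
        spec = config.family_composition.get(sub)
        age = spec.age_rank if spec else UNRANKED_AGE_RANK
        for _ in range(n_fl):
            length = int(rng.integers(config.fl_length_range[0],
                                      config.fl_length_range[1] + 1))
            items.append(("te", new_id(sub), sub, length, age))
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_length_range[0],
                                  config.gene_length_range[1] + 1))
        items.append(("gene", f"GENE{i + 1:05d}", "", length, -1))

    order = rng.permutation(len(items))
    chrom_of = rng.integers(0, config.n_chroms, size=len(items))
    margin = config.ectopic_block_spec[1] + 50_000  # keep chrom ends TE-free
    usable = config.chrom_length_bp - 2 * margin
    elements: list[TEElement] = []
    genes: list[Gene] = []
    sub2class = {s: spec.te_class for s, spec in config.family_composition.items()}
    for c, chrom in enumerate(config.chrom_names()):
        idx = [int(i) for i in order if chrom_of[i] == c]
        total = sum(items[i][3] for i in idx)
        free = usable - total
        if free <= len(idx):
            raise ValueError(
                f"infeasible packing on {chrom}: {total} bp of features in "
                f"{usable} bp of usable sequence")
        gaps = rng.dirichlet(np.ones(len(idx) + 1)) * free
        pos = margin
        for k, i in enumerate(idx):
            pos += int(gaps[k])
            kind, ident, sub, length, age = items[i]
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, pos, pos + length, strand)
            if kind == "te":
                elements.append(TEElement(ident, iv, sub2class[sub], sub, age_rank=age))
            else:
                genes.append(Gene(ident, iv))
            pos += length
    age_order = [s for s, spec in sorted(config.family_composition.items(),
                                         key=lambda kv: kv[1].age_rank)
                 if spec.age_rank < UNRANKED_AGE_RANK]
    catalog = TECatalog(elements, sub2class, age_order)
    return classify_full_length(catalog), genes


# -- peaks ------------------------------------------------------------------

def simulate_peaks(config: SimConfig, catalog: TECatalog,
                   rng: np.random.Generator):
    """Control peaks over young FL-L1s plus background; treatment loses a
    configurable fraction and gains ectopic chromosome-end blocks."""
    jit_lo, jit_hi = config.peak_jitter_bp
    candidates: list[tuple[str, int, int, float, str]] = []
    for locus_id in young_fl_l1_ids(catalog):
        iv = catalog.by_id(locus_id).interval
        s = max(0, iv.start - int(rng.integers(jit_lo, jit_hi)))
        e = iv.end + int(rng.integers(jit_lo, jit_hi))
        candidates.append((iv.chrom, s, e, float(rng.uniform(5, 20)), locus_id))
    lo, hi = config.background_peak_length
    margin = config.ectopic_block_spec[1] + 50_000  # chrom ends host ectopic blocks
    for _ in range(config.n_background_peaks):
        chrom = config.chrom_names()[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(margin, config.chrom_length_bp - margin - length))
        candidates.append((chrom, start, start + length,
                           float(rng.uniform(2, 10)), "background"))

    # a peak caller reports disjoint peaks per condition: trim collisions,
    # dropping candidates squeezed under the background minimum length
    candidates.sort(key=lambda c: (c[0], c[1]))
    control: list[Peak] = []
    origin: list[str] = []
    prev_chrom, prev_end = "", 0
    for chrom, s, e, score, who in candidates:
        if chrom == prev_chrom:
            s = max(s, prev_end)
        if e - s < lo:
            continue
        control.append(Peak(GenomicInterval(chrom, s, e), score))
        origin.append(who)
        prev_chrom, prev_end = chrom, e

    lost = rng.random(len(control)) < config.peak_loss_fraction
    treatment = [p for p, l in zip(control, lost) if not l]
    n_blocks, block_len = config.ectopic_block_spec
    for chrom in config.chrom_names():
        ends = [(0, block_len), (config.chrom_length_bp - block_len,
                                 config.chrom_length_bp)]
        for s, e in ends[:n_blocks]:
            treatment.append(Peak(GenomicInterval(chrom, s, e),
                                  float(rng.uniform(10, 30))))
    truth = pd.DataFrame({
        "chrom": [p.interval.chrom for p in control],
        "start": [p.interval.start for p in control],
        "end": [p.interval.end for p in control],
        "origin": origin,
        "fate": np.where(lost, "lost", "kept"),
    })
    return (PeakSet("control", "rep1", control),
            PeakSet("treatment", "rep1", treatment), truth)


def simulate_signal_tracks(config: SimConfig, catalog: TECatalog,
                           control_peaks: PeakSet, treatment_peaks: PeakSet,
                           activated_ids: list[str], rng: np.random.Generator):
    """bedGraph-style tracks: repressive mark following the peak sets, and an
    activating promoter mark at young FL-L1 5' ends in treatment, tiered
    high / low / none (ground truth for confidence calls)."""
    young = young_fl_l1_ids(catalog)
    tiers: dict[str, str] = {}
    activated = set(activated_ids)
    non_planted = [i for i in young if i not in activated]
    n_low = int(round(config.frac_low_tier * len(non_planted)))
    low_ids = ({str(x) for x in rng.choice(non_planted, size=n_low, replace=False)}
               if n_low else set())
    for i in young:
        tiers[i] = "high" if i in activated else ("low" if i in low_ids else "none")

    bin_bp = config.signal_bin_bp
    lo, hi = config.signal_noise_range

    def peak_track(peaks: PeakSet) -> list[tuple[str, int, int, float]]:
        rows = []
        for chrom in config.chrom_names():
            n_bins = config.chrom_length_bp // bin_bp
            vals = rng.uniform(lo, hi, size=n_bins)
            for p in peaks:
                if p.interval.chrom != chrom:
                    continue
                b0 = p.interval.start // bin_bp
                b1 = min((p.interval.end + bin_bp - 1) // bin_bp, n_bins)
                vals[b0:b1] += config.peak_signal_value
            rows.extend((chrom, b * bin_bp, (b + 1) * bin_bp, round(float(v), 4))
                        for b, v in enumerate(vals))
        return rows

    def promoter_track() -> list[tuple[str, int, int, float]]:
        amp_of: dict[str, float] = {}
        for i in young:
            if tiers[i] == "high":
                amp_of[i] = float(rng.uniform(*config.promoter_high_amp))
            elif tiers[i] == "low":
                amp_of[i] = float(rng.uniform(*config.promoter_low_amp))
        rows = []
        for chrom in config.chrom_names():
            n_bins = config.chrom_length_bp // bin_bp
            vals = rng.uniform(lo, hi, size=n_bins)
            for i in young:
                e = catalog.by_id(i)
                if i not in amp_of:
                    continue
                iv = e.interval
                if iv.chrom != chrom:
                    continue
                if iv.strand == "+":
                    s, t = iv.start, min(iv.start + config.promoter_signal_bp, iv.end)
                else:
                    s, t = max(iv.end - config.promoter_signal_bp, iv.start), iv.end
                vals[s // bin_bp:(t + bin_bp - 1) // bin_bp] = amp_of[i]
            rows.extend((chrom, b * bin_bp, (b + 1) * bin_bp, round(float(v), 4))
                        for b, v in enumerate(vals))
        return rows

    tracks = {
        "h3k9me3_control": peak_track(control_peaks),
        "h3k9me3_treatment": peak_track(treatment_peaks),
        "h3k4me3_treatment": promoter_track(),
    }
    return tracks, tiers


# -- expression -------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    mean = np.maximum(mean, 1e-8)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(config: SimConfig, catalog: TECatalog, genes: list[Gene],
                    rng: np.random.Generator):
    """Negative-binomial stranded TE counts + gene counts + emulated DE tables.

    90% of genes are non-DE; a seeded fraction of young FL-L1s is activated
    in treatment (mean shifted by ``activation_lfc`` log2 units, sense share
    ``sense_bias``). The DE table mirrors an external DE engine's columns
    and is consistent with the planted truth: small padj (<0.01) at planted
    loci, padj ~ U(0.1, 1) elsewhere.
    """
    samples = list(config.samples())
    groups = config.samples()
    depth = np.array([config.true_depth_factors.get(s, 1.0) for s in samples])
    is_treat = np.array([groups[s] == "treatment" for s in samples])

    # --- genes
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    g_mean = rng.lognormal(config.gene_log_mean, config.gene_log_sd, size=n_genes)
    de_mask = rng.random(n_genes) < config.frac_de_genes
    g_lfc = np.zeros(n_genes)
    n_de = int(de_mask.sum())
    g_lfc[de_mask] = rng.uniform(1.0, 3.0, size=n_de) * rng.choice([-1, 1], size=n_de)
    mean_grid = g_mean[:, None] * np.where(is_treat[None, :],
                                           2.0 ** g_lfc[:, None], 1.0) * depth[None, :]
    gene_counts = pd.DataFrame(_nb_draw(rng, mean_grid, config.nb_dispersion),
                               index=gene_ids, columns=samples)

    # --- TE loci
    locus_ids = [e.locus_id for e in catalog]
    n_loci = len(locus_ids)
    t_mean = rng.lognormal(config.te_log_mean, config.te_log_sd, size=n_loci)
    young = young_fl_l1_ids(catalog)
    n_act = int(round(config.frac_activated_young_L1 * len(young)))
    activated = (sorted(str(x) for x in rng.choice(young, size=n_act, replace=False))
                 if n_act else [])
    act_set = set(activated)
    t_lfc = np.array([config.activation_lfc if i in act_set else 0.0
                      for i in locus_ids])
    sense_share = np.array([config.sense_bias if i in act_set else 0.5
                            for i in locus_ids])
    total_mean = t_mean[:, None] * np.where(is_treat[None, :],
                                            2.0 ** t_lfc[:, None], 1.0) * depth[None, :]
    # sense bias applies where activation acts (treatment); control is balanced
    share_grid = np.where(is_treat[None, :], sense_share[:, None], 0.5)
    sense = _nb_draw(rng, total_mean * share_grid, config.nb_dispersion)
    antisense = _nb_draw(rng, total_mean * (1 - share_grid), config.nb_dispersion)
    te_counts = StrandedCountMatrix(locus_ids, samples, sense, antisense)

    # --- emulated DE tables (consistent with planted truth)
    def de_table(ids, true_lfc, base_mean, planted_mask):
        n = len(ids)
        lfc = true_lfc + rng.normal(0, 0.3, size=n)
        padj = np.where(planted_mask,
                        10.0 ** -rng.uniform(2.5, 8.0, size=n),
                        rng.uniform(0.1, 1.0, size=n))
        pvalue = padj * rng.uniform(0.1, 1.0, size=n)
        return pd.DataFrame({
            "locus_id": ids,
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "padj": padj,
        })

    te_base = (sense + antisense).mean(axis=1) / np.mean(depth)
    de_te = de_table(locus_ids, t_lfc,
                     te_base, np.array([i in act_set for i in locus_ids]))
    de_genes = de_table(gene_ids, g_lfc, gene_counts.mean(axis=1).to_numpy() /
                        np.mean(depth), de_mask)
    return te_counts, gene_counts, de_te, de_genes, list(activated)


# -- methylation ------------------------------------------------------------

def simulate_methylation(config: SimConfig, catalog: TECatalog,
                         activated_ids: list[str],
                         rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG 5mC/5hmC calls over full-length L1 loci for every sample.

    Per element and condition a latent modification level is drawn (5mC high
    in control, dropping at activated loci in treatment; 5hmC near zero in
    control, gaining at activated loci); per site, coverage ~ Poisson and
    modified calls ~ Binomial(coverage, level).
    """
    act = set(activated_ids)
    a_c, b_c = config.meth_control_beta
    a_t, b_t = config.meth_activated_treatment_beta
    c = config.hmc_concentration

    def beta_from_mean(mean: float) -> tuple[float, float]:
        return mean * c, (1 - mean) * c

    samples = config.samples()
    elements = [e for e in catalog if e.te_class == "L1" and e.full_length]
    rows = []
    truth_rows = []
    for e in elements:
        iv = e.interval
        positions = np.arange(iv.start, iv.end, config.cpg_spacing_bp)
        level = {}
        for cond in sorted(set(samples.values())):
            activated_here = cond == "treatment" and e.locus_id in act
            mc = rng.beta(a_t, b_t) if activated_here else rng.beta(a_c, b_c)
            hm_mean = (config.hmc_activated_mean if activated_here
                       else config.hmc_control_mean)
            hmc = rng.beta(*beta_from_mean(hm_mean))
            level[cond] = {"5mC": mc, "5hmC": hmc}
            truth_rows.append((e.locus_id, cond, mc, hmc,
                               e.locus_id in act))
        for sample, cond in samples.items():
            for channel in ("5mC", "5hmC"):
                cov = np.maximum(rng.poisson(config.coverage_lambda,
                                             size=len(positions)), 1)
                nmod = rng.binomial(cov, level[cond][channel])
                for p, cv, nm in zip(positions, cov, nmod):
                    rows.append((iv.chrom, int(p), iv.strand, channel,
                                 int(cv), int(nm), sample))
    calls = pd.DataFrame(rows, columns=SITE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=[
        "locus_id", "condition", "level_5mC", "level_5hmC", "activated"])
    return calls, truth


# -- bundle -----------------------------------------------------------------

def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator stage under one seeded random stream."""
    rng = np.random.default_rng(config.seed)
    catalog, genes = simulate_catalog(config, rng)
    control_peaks, treatment_peaks, peak_truth = simulate_peaks(config, catalog, rng)
    te_counts, gene_counts, de_te, de_genes, activated = simulate_counts(
        config, catalog, genes, rng)
    tracks, tiers = simulate_signal_tracks(
        config, catalog, control_peaks, treatment_peaks, activated, rng)
    meth_calls, meth_truth = simulate_methylation(config, catalog, activated, rng)
    return SimBundle(config, catalog, genes, control_peaks, treatment_peaks,
                     peak_truth, te_counts, gene_counts, de_te, de_genes,
                     activated, tiers, tracks, meth_calls, meth_truth)


def write_fixture_bundle(config: SimConfig, out_dir) -> dict:
    """Write the complete fixture to ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(config)
    manifest: dict = {"config_hash": bundle.config.config_hash(),
                      "seed": config.seed, "files": {}}

    def record(name: str, n_rows: int) -> None:
        manifest["files"][name] = {"rows": n_rows}

    with open(out / "te_catalog.gtf", "w") as fh:
        write_te_gtf(bundle.catalog, fh)
    record("te_catalog.gtf", len(bundle.catalog))
    with open(out / "te_catalog.bed", "w") as fh:
        write_bed6((e.interval for e in bundle.catalog), fh,
                   names=[e.locus_id for e in bundle.catalog])
    record("te_catalog.bed", len(bundle.catalog))
    with open(out / "genes.bed", "w") as fh:
        write_bed6((g.interval for g in bundle.genes), fh,
                   names=[g.gene_id for g in bundle.genes])
    record("genes.bed", len(bundle.genes))

    for name, peaks in [("peaks_control.bed", bundle.control_peaks),
                        ("peaks_treatment.bed", bundle.treatment_peaks)]:
        with open(out / name, "w") as fh:
            write_peaks_bed(peaks, fh)
        record(name, len(peaks))

    for name, rows in bundle.signal_tracks.items():
        fname = f"{name}.bedgraph"
        with open(out / fname, "w") as fh:
            for chrom, s, e, v in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
        record(fname, len(rows))

    sense, antisense = bundle.te_counts.to_frames()
    sense.rename_axis("locus_id").to_csv(out / "te_counts_sense.tsv", sep="\t")
    record("te_counts_sense.tsv", len(sense))
    antisense.rename_axis("locus_id").to_csv(out / "te_counts_antisense.tsv", sep="\t")
    record("te_counts_antisense.tsv", len(antisense))
    bundle.gene_counts.rename_axis("gene_id").to_csv(out / "gene_counts.tsv", sep="\t")
    record("gene_counts.tsv", len(bundle.gene_counts))
    bundle.de_te.to_csv(out / "de_te.tsv", sep="\t", index=False)
    record("de_te.tsv", len(bundle.de_te))
    bundle.de_genes.to_csv(out / "de_genes.tsv", sep="\t", index=False)
    record("de_genes.tsv", len(bundle.de_genes))

    samples = config.samples()
    with open(out / "samples.tsv", "w") as fh:
        for s, cond in samples.items():
            fh.write(f"{s}\t{cond}\n")
    record("samples.tsv", len(samples))

    for sample in samples:
        sub = bundle.meth_calls[bundle.meth_calls["sample_id"] == sample]
        fname = f"methylation_{sample}.bedmethyl"
        with open(out / fname, "w") as fh:
            write_bedmethyl(sub, fh)
        record(fname, len(sub))

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.Series(sorted(bundle.activated_ids)).to_csv(
        truth_dir / "activated_loci.tsv", sep="\t", index=False, header=False)
    record("truth/activated_loci.tsv", len(bundle.activated_ids))
    bundle.peak_truth.to_csv(truth_dir / "peak_fates.tsv", sep="\t", index=False)
    record("truth/peak_fates.tsv", len(bundle.peak_truth))
    pd.DataFrame(sorted(bundle.promoter_tiers.items()),
                 columns=["locus_id", "tier"]).to_csv(
        truth_dir / "promoter_tiers.tsv", sep="\t", index=False)
    record("truth/promoter_tiers.tsv", len(bundle.promoter_tiers))
    pd.DataFrame(sorted(config.true_depth_factors.items()),
                 columns=["sample_id", "depth"]).to_csv(
        truth_dir / "depth_factors.tsv", sep="\t", index=False)
    record("truth/depth_factors.tsv", len(config.true_depth_factors))
    bundle.meth_truth.to_csv(truth_dir / "methylation_levels.tsv",
                             sep="\t", index=False)
    record("truth/methylation_levels.tsv", len(bundle.meth_truth))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
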