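"""Orchestration: run the peak / enrichment / expression / methylation stages
on file inputs and emit a machine-readable report.

Each stage reads and writes only the documented text formats, so stages
compose via files and any report table can be re-derived by calling the
underlying module operation directly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, enrichment, expression, methylation, peaks

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "telocus_out"
    # inputs
    te_gtf: str | None = None
    genes_bed: str | None = None
    peaks_control: str | None = None
    peaks_treatment: str | None = None
    te_counts_sense: str | None = None
    te_counts_antisense: str | None = None
    gene_counts: str | None = None
    de_te: str | None = None
    de_genes: str | None = None
    samples_tsv: str | None = None
    bedmethyl: dict[str, str] = field(default_factory=dict)  # sample -> path
    # stage toggles
    run_peaks: bool = True
    run_enrichment: bool = True
    run_expression: bool = True
    run_methylation: bool = True
    # thresholds
    min_peak_length_bp: int = peaks.DEFAULT_MIN_PEAK_BP
    lfc_min: float = 0.0
    padj_max: float = 0.05
    base_mean_min: float = 1.0
    gene_abs_lfc_min: float = 1.0
    promoter_length_bp: int = annotation.DEFAULT_PROMOTER_BP
    min_coverage: int = methylation.DEFAULT_MIN_COVERAGE
    proximity_bp: int = 50_000
    enrichment_R: int = enrichment.DEFAULT_RESAMPLES
    enrichment_group_by: str = "subfamily"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of findings; empty means the config is runnable."""
    findings = []
    path_fields = ["te_gtf", "genes_bed", "peaks_control", "peaks_treatment",
                   "te_counts_sense", "te_counts_antisense", "gene_counts",
                   "de_te", "de_genes", "samples_tsv"]
    needed = set()
    if config.run_peaks:
        needed |= {"te_gtf", "peaks_control", "peaks_treatment"}
    if config.run_enrichment:
        needed |= {"te_gtf", "de_te"}
    if config.run_expression:
        needed |= {"te_gtf", "de_te", "gene_counts", "te_counts_sense",
                   "te_counts_antisense", "samples_tsv"}
    if config.run_methylation:
        needed |= {"te_gtf", "de_te", "samples_tsv"}
    for name in path_fields:
        value = getattr(config, name)
        if name in needed and value is None:
            findings.append(f"{name}: required by an enabled stage but unset")
        elif value is not None and not Path(value).exists():
            findings.append(f"{name}: file not found: {value}")
    for sample, path in config.bedmethyl.items():
        if not Path(path).exists():
            findings.append(f"bedmethyl[{sample}]: file not found: {path}")
    if config.run_methylation and not config.bedmethyl:
        findings.append("bedmethyl: required by the methylation stage but empty")
    if config.enrichment_R < 1:
        findings.append(f"enrichment_R: must be >= 1, got {config.enrichment_R}")
    if config.min_peak_length_bp < 0:
        findings.append("min_peak_length_bp: must be >= 0")
    if not 0 < config.padj_max <= 1:
        findings.append(f"padj_max: must be in (0, 1], got {config.padj_max}")
    if config.promoter_length_bp <= 0:
        findings.append("promoter_length_bp: must be positive")
    if config.enrichment_group_by not in {"class", "subfamily"}:
        findings.append("enrichment_group_by: must be 'class' or 'subfamily'")
    if config.seed is None:
        findings.append("seed: must be set for reproducible resampling")
    return findings


@dataclass
class Report:
    tables: dict[str, object] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = {"metadata": self.metadata, "tables": {}}
        for name, table in self.tables.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
                summary["tables"][name] = f"{name}.tsv"
            else:
                summary["tables"][name] = table
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)


def _load_groups(path: str) -> dict[str, str]:
    groups = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        sample, cond = line.split("\t")[:2]
        groups[sample] = cond
    return groups


def run_pipeline(config: RunConfig) -> Report:
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    report = Report(metadata={
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    })

    with open(config.te_gtf) as fh:
        catalog = annotation.classify_full_length(annotation.parse_te_gtf(fh))
    fl_young = [e for e in catalog
                if e.te_class == "L1" and e.full_length and e.age_rank <= 2]

    if config.run_peaks:
        try:
            with open(config.peaks_control) as fh:
                control = peaks.read_peaks_bed(fh, "control")
            with open(config.peaks_treatment) as fh:
                treatment = peaks.read_peaks_bed(fh, "treatment")
            control = peaks.filter_peaks(control, config.min_peak_length_bp)
            treatment = peaks.filter_peaks(treatment, config.min_peak_length_bp)
            _, class_summary = peaks.assign_peak_classes(control, catalog)
            n_control, n_lost, frac_lost = peaks.peak_retention(control, treatment)
            report.tables["peak_classes"] = class_summary
            report.tables["peak_retention"] = {
                "n_control": n_control, "n_lost": n_lost,
                "fraction_lost": frac_lost,
            }
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("peaks", str(exc)) from exc

    de_te = None
    if config.de_te:
        try:
            de_te = expression.read_de_table(config.de_te)
        except Exception as exc:  # noqa: BLE001
            raise StageError("expression", f"bad DE table: {exc}") from exc

    if config.run_enrichment:
        try:
            upregulated = expression.select_upregulated_tes(
                de_te, config.lfc_min, config.padj_max)
            results = enrichment.enrichment_analysis(
                upregulated, catalog, group_by=config.enrichment_group_by,
                R=config.enrichment_R, seed=config.seed)
            rows = pd.DataFrame(enrichment.results_to_rows(results))
            rows["enriched_significant"] = (
                (rows["observed"] > rows["expected_mean"])
                & (rows["p_two_sided"] < 0.01))
            report.tables["enrichment"] = rows
            report.tables["n_upregulated_tes"] = len(upregulated)
        except Exception as exc:
            raise StageError("enrichment", str(exc)) from exc

    if config.run_expression:
        try:
            groups = _load_groups(config.samples_tsv)
            gene_counts = pd.read_csv(config.gene_counts, sep="\t", index_col=0)
            sense = pd.read_csv(config.te_counts_sense, sep="\t", index_col=0)
            anti = pd.read_csv(config.te_counts_antisense, sep="\t", index_col=0)
            factors = expression.size_factors_median_of_ratios(gene_counts)
            counts = expression.StrandedCountMatrix(
                list(sense.index), list(sense.columns),
                sense.to_numpy(), anti.to_numpy())
            upregulated = expression.select_upregulated_tes(
                de_te, config.lfc_min, config.padj_max)
            detectable = expression.select_detectable(de_te, config.base_mean_min)
            fl_ids = {e.locus_id for e in fl_young}
            up_fl = upregulated & fl_ids & detectable
            summary = expression.sense_antisense_summary(
                counts, factors, groups, loci=up_fl or None)
            report.tables["size_factors"] = factors.factors
            report.tables["upregulated_fl_l1"] = {
                "n_detectable_fl_l1": len(detectable & fl_ids),
                "n_upregulated_fl_l1": len(up_fl),
                "percent_upregulated": (
                    expression.percent_of(len(up_fl), len(detectable & fl_ids))
                    if detectable & fl_ids else 0),
            }
            report.tables["sense_antisense"] = summary.reset_index(
                names="locus_id")
            if config.de_genes:
                de_g = expression.read_de_table(config.de_genes)
                up_g, down_g = expression.select_de_genes(
                    de_g, config.gene_abs_lfc_min, config.padj_max)
                report.tables["de_genes"] = {"n_up": len(up_g),
                                             "n_down": len(down_g)}
                if config.genes_bed:
                    genes = []
                    for line in Path(config.genes_bed).read_text().splitlines():
                        if not line.strip() or line.startswith(("#", "track")):
                            continue
                        c = line.split("\t")
                        genes.append(annotation.Gene(
                            c[3], annotation.GenomicInterval(
                                c[0], int(c[1]), int(c[2]), c[5])))
                    proximal = expression.genes_near_elements(
                        genes, fl_young, config.proximity_bp)
                    distal = {g.gene_id for g in genes} - proximal
                    u, p = expression.compare_lfc(proximal, distal, de_g)
                    report.tables["proximity_lfc"] = {
                        "n_proximal": len(proximal), "n_distal": len(distal),
                        "U": u, "p_two_sided": p,
                    }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("expression", str(exc)) from exc

    if config.run_methylation:
        try:
            groups = _load_groups(config.samples_tsv)
            upregulated = expression.select_upregulated_tes(
                de_te, config.lfc_min, config.padj_max)
            fl_ids = {e.locus_id for e in fl_young}
            targets = sorted(upregulated & fl_ids)
            results = {}
            for channel in ("5mC", "5hmC"):
                summaries = []
                for sample, path in config.bedmethyl.items():
                    with open(path) as fh:
                        calls = methylation.read_bedmethyl(fh, channel, sample)
                    for locus_id in targets:
                        e = catalog.by_id(locus_id)
                        window = annotation.promoter_window(
                            e, config.promoter_length_bp)
                        summaries.append(methylation.window_methylation(
                            calls, window, region_id=locus_id,
                            sample_id=sample, channel=channel,
                            min_coverage=config.min_coverage))
                comparison, stats_out = methylation.compare_conditions(
                    summaries, groups, set(targets), channel)
                results[channel] = {
                    "W": comparison.W_statistic,
                    "p_two_sided": comparison.p_two_sided,
                    "n_pairs": comparison.n_pairs_used,
                    **stats_out,
                }
            report.tables["promoter_methylation"] = results
        except StageError:
            raise
        except Exception as exc:
            raise StageError("methylation", str(exc)) from exc

    return report
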