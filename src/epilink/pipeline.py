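"""End-to-end orchestration: config, validation, and the run-all driver.

The stage funnel mirrors the analysis: epithelial quantification ->
peak-phenotype screen -> peak-to-gene linking -> enrichment -> survival.
Every run writes per-stage TSVs, the resolved config, and a JSON report with
the record counts flowing through each stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, image_quant, io, linking, screen, survival
from .errors import EpilinkError, StageError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds default to the published analysis constants."""

    # inputs
    cohort_tsv: str | None = None
    proportions_tsv: str | None = None
    masks_dir: str | None = None
    accessibility_tsv: str | None = None
    peaks_tsv: str | None = None
    genes_tsv: str | None = None
    expression_tsv: str | None = None
    copy_number_tsv: str | None = None
    gmt: str | None = None
    survival_tsv: str | None = None
    # optional distinct follow-up cohort (defaults to the screen cohort's data)
    survival_expression_tsv: str | None = None
    survival_cohort_tsv: str | None = None
    # outputs
    outdir: str = "epilink_out"
    # thresholds
    alpha: float = 0.05
    distal_fdr_cut: float = 0.01
    max_dist: int = 500_000
    promoter_far: int = 1000
    promoter_near: int = 100
    epithelial_cutoff: float = 0.5
    pvalue_method: str = "approximate"
    cnv_attenuation: float = 0.5
    rho_threshold: float | None = None
    survival_alpha: float = 0.05
    include_image_feature: bool = True
    zscore_features: bool = True
    seed: int = 0

    def validate(self) -> None:
        checks = [
            0.0 <= self.alpha <= 1.0,
            0.0 <= self.distal_fdr_cut <= 1.0,
            self.max_dist > 0,
            self.promoter_far > self.promoter_near >= 0,
            0.0 <= self.epithelial_cutoff <= 1.0,
            self.pvalue_method in ("approximate", "auto", "exhaustive", "montecarlo"),
            self.cnv_attenuation >= 0.0,
            0.0 <= self.survival_alpha <= 1.0,
        ]
        if not all(checks):
            raise EpilinkError("config thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise EpilinkError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class Finding:
    level: str  # "warning" | "fatal"
    message: str


def validate_inputs(config: PipelineConfig) -> list[Finding]:
    """Pre-flight checks; returns findings instead of raising."""
    findings: list[Finding] = []

    def _exists(path, label) -> bool:
        if path is None:
            return False
        if not Path(path).exists():
            findings.append(Finding("fatal", f"{label} not found: {path}"))
            return False
        return True

    cohort = None
    if _exists(config.cohort_tsv, "cohort_tsv"):
        try:
            cohort = io.read_cohort(config.cohort_tsv)
        except EpilinkError as exc:
            findings.append(Finding("fatal", f"cohort_tsv: {exc}"))
    peaks = None
    if _exists(config.peaks_tsv, "peaks_tsv"):
        try:
            peaks = io.read_peaks(config.peaks_tsv)
        except EpilinkError as exc:
            findings.append(Finding("fatal", f"peaks_tsv: {exc}"))
    if _exists(config.genes_tsv, "genes_tsv"):
        try:
            io.read_genes(config.genes_tsv)
        except EpilinkError as exc:
            findings.append(Finding("fatal", f"genes_tsv: {exc}"))
    if _exists(config.accessibility_tsv, "accessibility_tsv") and cohort is not None:
        acc_cols = pd.read_csv(config.accessibility_tsv, sep="\t", nrows=0).columns[1:]
        missing = set(cohort["sample_id"]) - set(acc_cols)
        if missing:
            findings.append(Finding(
                "warning",
                f"accessibility matrix missing {len(missing)} cohort samples; "
                "inner join on shared samples will be used"))
    if peaks is not None and config.accessibility_tsv and Path(config.accessibility_tsv).exists():
        acc_ids = pd.read_csv(config.accessibility_tsv, sep="\t", usecols=[0]).iloc[:, 0]
        if set(acc_ids) != set(peaks["peak_id"]):
            findings.append(Finding(
                "warning", "peak table and accessibility matrix ids differ; intersection used"))
    return findings


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    report: dict = {"stages": {}}

    # ---- stage 1: epithelial quantification -------------------------------
    try:
        if config.cohort_tsv:
            cohort = io.read_cohort(config.cohort_tsv)
            if "group" not in cohort.columns:
                cohort = image_quant.build_cohort(cohort, config.epithelial_cutoff)
        elif config.proportions_tsv:
            cohort = image_quant.build_cohort(io.read_cohort(config.proportions_tsv),
                                              config.epithelial_cutoff)
        elif config.masks_dir:
            masks = {p.stem: p for p in sorted(Path(config.masks_dir).glob("*.png"))}
            cohort = image_quant.cohort_from_masks(masks, config.epithelial_cutoff)
        else:
            raise EpilinkError("no cohort source configured "
                               "(cohort_tsv / proportions_tsv / masks_dir)")
        io.write_cohort(cohort, outdir / "cohort.tsv")
        n_low, n_high, low_frac = image_quant.cohort_summary(cohort)
        report["stages"]["image_quant"] = {
            "n_samples": len(cohort), "n_low": n_low, "n_high": n_high,
            "low_fraction": low_frac,
        }
    except EpilinkError as exc:
        raise StageError("image_quant", str(exc)) from exc

    # ---- stage 2: peak-phenotype screen -----------------------------------
    try:
        acc = io.read_matrix_tsv(config.accessibility_tsv)
        peaks = io.read_peaks(config.peaks_tsv) if config.peaks_tsv else None
        results = screen.screen_peaks(
            acc, cohort, alpha=config.alpha, peaks=peaks,
            method=config.pvalue_method, rho_threshold=config.rho_threshold,
            seed=config.seed)
        results.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
        counts = screen.screen_counts(results)
        report["stages"]["screen"] = counts
        log.info("screen: %(peaks_tested)d tested -> %(significant)d significant "
                 "(%(positive)d positive / %(negative)d negative)", counts)
    except EpilinkError as exc:
        raise StageError("screen", str(exc)) from exc

    # ---- stage 3: peak-to-gene linking ------------------------------------
    try:
        genes = io.read_genes(config.genes_tsv)
        expr = io.read_matrix_tsv(config.expression_tsv)
        cn = io.read_matrix_tsv(config.copy_number_tsv) if config.copy_number_tsv else None
        sig_ids = results.loc[results["significant"], "peak_id"]
        sig_peaks = (peaks[peaks["peak_id"].isin(sig_ids)].reset_index(drop=True)
                     if peaks is not None else None)
        if sig_peaks is None:
            raise EpilinkError("peaks_tsv with coordinates is required for linking")
        promoter_links = linking.assign_promoter_peaks(
            sig_peaks, genes, far=config.promoter_far, near=config.promoter_near)
        pairs = linking.candidate_distal_pairs(sig_peaks, genes, max_dist=config.max_dist)
        pairs = linking.annotate_pairs_with_summits(pairs, sig_peaks)
        windows = linking.build_promoter_windows(genes, far=config.promoter_far,
                                                 near=config.promoter_near)
        distal_links = linking.link_distal(
            pairs, acc, expr, cn=cn, fdr_cut=config.distal_fdr_cut,
            cnv_attenuation=config.cnv_attenuation, promoter_windows=windows)
        all_links = pd.concat([promoter_links.assign(survives=True), distal_links],
                              ignore_index=True)
        all_links.to_csv(outdir / "links.tsv", sep="\t", index=False)
        targets = linking.collapse_targets(promoter_links, distal_links, expr, cohort)
        targets.to_csv(outdir / "target_genes.tsv", sep="\t", index=False)
        report["stages"]["linking"] = {
            "promoter_links": int(len(promoter_links)),
            "distal_pairs_tested": int(len(distal_links)),
            "distal_links_surviving": int(distal_links["survives"].sum())
            if len(distal_links) else 0,
            "target_genes": int(len(targets)),
            "target_genes_positive": int((targets["sign"] == "positive").sum()),
            "target_genes_negative": int((targets["sign"] == "negative").sum()),
        }
    except EpilinkError as exc:
        raise StageError("linking", str(exc)) from exc

    # ---- stage 4: enrichment (optional) -----------------------------------
    if config.gmt:
        try:
            sets = io.read_gmt(config.gmt)
            collection = enrichment.GeneSetCollection(sets, set(expr.index.astype(str)))
            enr = enrichment.enrich_by_sign(targets, collection)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["stages"]["enrichment"] = {
                "sets_tested": int(enr["set_name"].nunique()) if len(enr) else 0,
                "sets_fdr05": int((enr["fdr"] < 0.05).sum()) if len(enr) else 0,
            }
        except EpilinkError as exc:
            raise StageError("enrichment", str(exc)) from exc

    # ---- stage 5: survival -------------------------------------------------
    if config.survival_tsv:
        try:
            records = io.read_survival(config.survival_tsv)
            surv_expr = (io.read_matrix_tsv(config.survival_expression_tsv)
                         if config.survival_expression_tsv else expr)
            surv_cohort = (io.read_cohort(config.survival_cohort_tsv)
                           if config.survival_cohort_tsv else cohort)
            features = surv_expr.loc[surv_expr.index.isin(targets["gene_id"])].copy()
            if config.include_image_feature:
                prop = surv_cohort.set_index("sample_id")["proportion"]
                shared = [s for s in features.columns if s in prop.index]
                image_row = pd.DataFrame(
                    [prop.loc[shared]], index=["epithelial_proportion"])
                features = pd.concat([features[shared], image_row])
            uni = survival.univariate_screen(features, records,
                                             alpha=config.survival_alpha)
            uni.to_csv(outdir / "univariate_survival.tsv", sep="\t", index=False)
            gene_rows = uni[uni["feature"] != "epithelial_proportion"]
            sig_feats = uni.loc[uni["significant"], "feature"].tolist()
            report["stages"]["survival"] = {
                "features_tested": int(len(uni)),
                "genes_significant": int(gene_rows["significant"].sum()),
                "image_feature_significant": bool(
                    uni.loc[uni["feature"] == "epithelial_proportion", "significant"].any()),
            }
            if sig_feats:
                grouping, p = survival.multivariate_stratify(
                    features.loc[sig_feats], records, seed=config.seed,
                    zscore=config.zscore_features)
                grouping.rename_axis("sample_id").reset_index().to_csv(
                    outdir / "risk_groups.tsv", sep="\t", index=False)
                report["stages"]["survival"]["multivariate_logrank_p"] = p
        except EpilinkError as exc:
            raise StageError("survival", str(exc)) from exc

    io.write_json(report, outdir / "report.json")
    return report
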