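"""End-to-end orchestration: QC -> LD scores -> enrichment -> CT-FM ->
SNP fine-mapping -> CT-FM-SNP -> quadruplets.

A :class:`RunConfig` names the input files and thresholds for one cancer;
:func:`run_pipeline` executes the stage sequence, writing every
intermediate table into the run directory so stages can be inspected and
re-run, plus a provenance record (config hash, seed, per-stage row
counts).  An optional exclusion list re-runs the context-level stages on
the reduced annotation library (sensitivity analysis) alongside the
primary results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ctfm.annotations import load_annotation_library, build_membership, subset_library
from ctfm.contexts import run_ctfm, classify_contexts
from ctfm.ldscore import (
    LDScoreMatrix,
    annotation_correlation,
    compute_ld_scores,
    multiple_testing,
    stratified_regression,
)
from ctfm.quadruplets import best_context_per_pair, join_quadruplets
from ctfm.snp_contexts import eligible_variants, run_ctfm_snp, summarize_contexts
from ctfm.snpfm import dedup_central, finemap_region, attach_priors, region_ld, tile_regions
from ctfm.sumstats import (
    ReferencePanel,
    align_to_reference,
    apply_qc_filters,
    effective_sample_size,
    read_sumstats,
)

log = logging.getLogger("ctfm")


@dataclass
class RunConfig:
    """All paths and thresholds for one cancer's run."""

    cancer_label: str
    sumstats: str
    panel: str
    annotation_manifest: str
    baseline_manifest: str | None = None
    priors: str | None = None
    cs2g: str | None = None
    out_dir: str = "ctfm_run"
    # QC thresholds
    info_min: float = 0.9
    maf_min: float = 0.005
    beta_max: float = 3.0
    maf_diff_max: float = 0.2
    # fine-mapping constants
    sig_threshold: float = 5e-8
    pip_high: float = 0.5
    pip_candidate: float = 0.05
    s2g_min: float = 0.5
    L_ctfm: int = 10
    L_snp: int = 5
    coverage: float = 0.95
    purity: str | float = "auto"
    snp_purity: float = 0.5
    region_size_bp: int = 3_000_000
    region_step_bp: int = 1_500_000
    window_bp: int = 1_000_000
    n_blocks: int | None = None
    seed: int = 0
    exclude_source: str | None = None
    exclude_names: list[str] = field(default_factory=list)
    dialect: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Human-readable problems; empty list when the config is runnable."""
    problems: list[str] = []
    for attr in ("sumstats", "panel", "annotation_manifest"):
        path = getattr(config, attr)
        if not Path(path).exists():
            problems.append(f"{attr}: path does not exist: {path}")
    for attr in ("baseline_manifest", "priors", "cs2g"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            problems.append(f"{attr}: path does not exist: {path}")
    for attr, lo, hi in [
        ("info_min", 0, 1),
        ("maf_min", 0, 0.5),
        ("maf_diff_max", 0, 1),
        ("pip_high", 0, 1),
        ("pip_candidate", 0, 1),
        ("s2g_min", 0, 1),
        ("coverage", 0, 1),
        ("snp_purity", 0, 1),
    ]:
        v = getattr(config, attr)
        if not (lo <= v <= hi):
            problems.append(f"{attr}: {v} outside [{lo}, {hi}]")
    if config.pip_candidate > config.pip_high:
        problems.append("pip_candidate exceeds pip_high")
    if config.region_step_bp > config.region_size_bp:
        problems.append("region_step_bp exceeds region_size_bp (windows would not overlap)")
    if config.L_ctfm < 1 or config.L_snp < 1:
        problems.append("L_ctfm and L_snp must be positive")
    if isinstance(config.purity, str) and config.purity != "auto":
        problems.append(f"purity must be 'auto' or a number, got {config.purity!r}")
    return problems


def _load_library_from_manifest(manifest_path: str | Path):
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    paths = []
    for fname in manifest["file"]:
        cand = [base / fname, base / "annotations" / fname, base / "baseline" / fname]
        hit = next((p for p in cand if p.exists()), None)
        if hit is None:
            raise FileNotFoundError(f"BED file not found for manifest entry {fname}")
        paths.append(hit)
    return load_annotation_library(paths, manifest)


def _subset_ld(ld: LDScoreMatrix, keep_contexts: list[str]) -> LDScoreMatrix:
    cols = ["base", *ld.baseline_names, *keep_contexts]
    idx = [ld.column_names.index(c) for c in cols]
    return LDScoreMatrix(
        values=ld.values[:, idx],
        variant_ids=ld.variant_ids,
        column_names=cols,
        baseline_names=ld.baseline_names,
        context_names=keep_contexts,
        annot=ld.annot[:, idx],
        window_bp=ld.window_bp,
    )


def _context_stages(
    out: Path,
    cancer: str,
    enrich: pd.DataFrame,
    corr,
    membership,
    causal_ids: list[str],
    config: RunConfig,
    counts: dict[str, int],
    prefix: str = "",
) -> None:
    """CT-FM, CT-FM-SNP and quadruplets; shared by primary and sensitivity runs."""
    contexts = run_ctfm(
        enrich, corr, L=config.L_ctfm, coverage=config.coverage, purity=config.purity, cancer=cancer
    )
    contexts.to_csv(out / f"{prefix}ctfm_contexts.tsv", sep="\t", index=False)
    classify_contexts(contexts).to_csv(out / f"{prefix}ctfm_summary.tsv", sep="\t", index=False)
    counts[f"{prefix}ctfm_high_confidence"] = int((contexts["tier"] == "high_confidence").sum())

    parts = eligible_variants(causal_ids, membership, enrich)
    triplets_list = []
    for vid in parts["tested"]:
        triplets_list.append(
            run_ctfm_snp(
                vid, enrich, corr, membership,
                L=config.L_ctfm, coverage=config.coverage, purity=config.purity, cancer=cancer,
            )
        )
    triplets = (
        pd.concat(triplets_list, ignore_index=True)
        if triplets_list
        else pd.DataFrame(
            columns=["variant_id", "annotation", "cancer", "pip", "n_overlapping",
                     "credible_set_id", "duplicate_of"]
        )
    )
    triplets.to_csv(out / f"{prefix}triplets.tsv", sep="\t", index=False)
    summary = summarize_contexts(triplets, pip_min=config.pip_high)
    summary.to_csv(out / f"{prefix}triplet_summary.tsv", sep="\t", index=False)
    counts[f"{prefix}snps_tested"] = len(parts["tested"])
    counts[f"{prefix}snps_single_overlap"] = len(parts["single_overlap"])
    counts[f"{prefix}triplets_high_confidence"] = int((triplets["pip"] >= config.pip_high).sum())

    if config.cs2g is not None:
        links = pd.read_csv(config.cs2g, sep="\t")
        quads = join_quadruplets(triplets, links, pip_min=config.pip_high, s2g_min=config.s2g_min)
        quads.to_csv(out / f"{prefix}quadruplets.tsv", sep="\t", index=False)
        best_context_per_pair(quads).to_csv(out / f"{prefix}best_context.tsv", sep="\t", index=False)
        counts[f"{prefix}quadruplets"] = len(quads)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages for one cancer; returns the run directory."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    counts: dict[str, int] = {}
    stage = "sumstats_qc"
    try:
        records = read_sumstats(config.sumstats, dialect=config.dialect or None)
        qc, qc_report = apply_qc_filters(
            records, info_min=config.info_min, maf_min=config.maf_min, beta_max=config.beta_max
        )
        panel = ReferencePanel.load(config.panel)
        harmonized, align_report = align_to_reference(qc, panel, maf_diff_max=config.maf_diff_max)
        (out / "qc_report.txt").write_text(qc_report.to_text() + align_report.to_text())
        harmonized.to_csv(out / "harmonized.tsv", sep="\t", index=False)
        counts["variants_input"] = qc_report.n_input
        counts["variants_harmonized"] = len(harmonized)
        log.info("QC: %d -> %d variants", qc_report.n_input, len(harmonized))

        stage = "annotation_membership"
        library = _load_library_from_manifest(config.annotation_manifest)
        membership = build_membership(harmonized, library)
        baseline = None
        if config.baseline_manifest:
            baseline_lib = _load_library_from_manifest(config.baseline_manifest)
            baseline = build_membership(harmonized, baseline_lib)

        stage = "ld_scores"
        ld = compute_ld_scores(panel, membership, baseline, window_bp=config.window_bp)

        stage = "enrichment"
        n_case = int(harmonized["n_case"].iloc[0])
        n_control = int(harmonized["n_control"].iloc[0])
        n_eff_ldsc = effective_sample_size(n_case, n_control, "ldsc")
        chisq = (harmonized["beta"] / harmonized["se"]).to_numpy() ** 2
        enrich = stratified_regression(chisq, ld, n_eff_ldsc, n_blocks=config.n_blocks)
        enrich = multiple_testing(enrich)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        counts["annotations_tested"] = len(enrich)

        stage = "annotation_correlation"
        corr = annotation_correlation(ld)
        corr.to_frame().to_csv(out / "annotation_correlation.tsv", sep="\t")

        stage = "snp_finemap"
        regions = tile_regions(
            harmonized,
            size_bp=config.region_size_bp,
            step_bp=config.region_step_bp,
            sig_threshold=config.sig_threshold,
        )
        counts["regions"] = len(regions)
        priors_table = None
        if config.priors:
            priors_table = pd.read_csv(config.priors, sep="\t").set_index("variant_id")[
                "per_snp_h2"
            ]
        n_eff_fm = effective_sample_size(n_case, n_control, "finemap")
        zmap = pd.Series(
            (harmonized["beta"] / harmonized["se"]).to_numpy(),
            index=harmonized["variant_id"],
        )
        region_results = []
        for region in regions:
            h2 = (
                priors_table.reindex(region.variant_index).fillna(0.0).to_numpy()
                if priors_table is not None
                else None
            )
            pri = attach_priors(region, h2)
            z = zmap.reindex(region.variant_index).to_numpy()
            R = region_ld(panel, region)
            region_results.append(
                finemap_region(
                    region, z, R, pri, n_eff_fm,
                    L=config.L_snp, coverage=config.coverage, purity_min=config.snp_purity,
                )
            )
        snp_results = (
            dedup_central(
                pd.concat(region_results, ignore_index=True),
                harmonized.set_index("variant_id")["position"],
            )
            if region_results
            else pd.DataFrame(
                columns=["variant_id", "chromosome", "region_start", "region_end",
                         "prior_prob", "pip", "credible_set_id", "high_confidence", "n_eff"]
            )
        )
        snp_results.to_csv(out / "snp_finemap.tsv", sep="\t", index=False)
        causal_ids = list(snp_results.loc[snp_results["pip"] >= config.pip_high, "variant_id"])
        counts["causal_snps"] = len(causal_ids)

        stage = "context_finemap"
        _context_stages(out, config.cancer_label, enrich, corr, membership, causal_ids, config, counts)

        if config.exclude_source or config.exclude_names:
            stage = "sensitivity"
            sens_dir = out / "sensitivity"
            sens_dir.mkdir(exist_ok=True)
            kept_lib = subset_library(
                library,
                exclude_source=config.exclude_source,
                exclude_names=config.exclude_names or None,
            )
            kept_names = [a.name for a in kept_lib]
            sens_membership = build_membership(harmonized, kept_lib)
            sens_ld = _subset_ld(ld, kept_names)
            sens_enrich = enrich[enrich["annotation"].isin(kept_names)].reset_index(drop=True)
            sens_corr = annotation_correlation(sens_ld)
            _context_stages(
                sens_dir, config.cancer_label, sens_enrich, sens_corr,
                sens_membership, causal_ids, config, counts, prefix="",
            )
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %s", stage)
        raise

    provenance = {"config_sha256": config.digest(), "seed": config.seed, **counts}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return out
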