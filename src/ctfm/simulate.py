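"""Deterministic synthetic inputs with known causal ground truth.

Emulates the four input classes the pipeline consumes — a genotype
reference panel, an annotation library, GWAS summary statistics, and
per-SNP priors / SNP-gene links — at desk scale, with the causal
annotation(s) and causal variants exposed for recovery tests.

The panel is a Gaussian-copula construction: per chromosome, latent
standard-normal sequences with exponential autocorrelation
``exp(-d / ld_decay_bp)`` (an Ornstein-Uhlenbeck chain, so the latent
correlation is exactly exponential in distance) are thresholded into
haplotypes at the target minor-allele frequency; the dosage is the sum of
two haplotypes.  Annotations are unions of fixed-width genomic segments;
correlation between annotation memberships is induced by letting each
annotation copy segments from a shared template with probability
``sqrt(annotation_corr_target)``, which gives pairwise membership
correlation ~= ``annotation_corr_target``.

Summary statistics are simulated directly in the z-score (RSS)
parameterization the pipeline operates in:  ``z = sqrt(n_eff) * R beta +
eps`` with ``eps ~ N(0, R)`` for the empirical panel LD ``R`` — per-SNP
heritability is ``proportional to 1 + (enrichment_fold - 1)`` inside a
causal annotation, normalized to ``h2_total``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ctfm.annotations import Annotation, MembershipMatrix, build_membership
from ctfm.sumstats import ReferencePanel, effective_sample_size

# non-strand-ambiguous allele pairs (other, counted)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass
class SimConfig:
    """Synthetic study conditions.

    Defaults are the desk-scale regime the test suite runs at: 2
    chromosomes x 5,000 variants x 500 panel samples x 40 annotations,
    one causal annotation at 5-fold per-SNP heritability enrichment,
    ~1,000 causal variants, total SNP heritability 0.5 and a 100k/100k
    case-control GWAS — chosen so the causal annotation's enrichment
    z-score falls in the range real context scans report for their top
    contexts.
    """

    seed: int = 0
    n_samples: int = 500
    n_variants: int = 10_000
    n_chromosomes: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_bp: float = 50_000.0
    mean_spacing_bp: int = 10_000
    n_annotations: int = 40
    annotation_coverage: float = 0.2
    annotation_corr_target: float = 0.2
    causal_annotations: list[str] = field(default_factory=lambda: ["context_000"])
    enrichment_fold: float = 5.0
    h2_total: float = 0.5
    n_causal_snps: int = 1000
    n_case: int = 100_000
    n_control: int = 100_000
    prior_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.annotation_coverage < 1:
            raise ValueError("annotation_coverage must be in (0, 1)")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if not 0 <= self.h2_total < 1:
            raise ValueError("h2_total must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def annotation_names(self) -> list[str]:
        return [f"context_{i:03d}" for i in range(self.n_annotations)]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated architecture."""

    causal_annotation_names: list[str]
    causal_variant_ids: list[str]
    per_snp_h2: np.ndarray
    true_beta: np.ndarray

    def realized_enrichment(self, member_mask: np.ndarray) -> float:
        """Share of realized h2 inside a mask over its share of variants."""
        b2 = self.true_beta**2
        tot = float(b2.sum())
        if tot == 0:
            return np.nan
        prop = member_mask.mean()
        return (float(b2[member_mask > 0].sum()) / tot) / prop


def simulate_panel(config: SimConfig) -> ReferencePanel:
    """Gaussian-copula reference panel with exponential LD decay."""
    if config.n_samples < 3:
        raise ValueError("n_samples must be at least 3")
    rng = config.rng(0)
    n_hap = 2 * config.n_samples
    per_chrom = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per_chrom[: config.n_variants % config.n_chromosomes] += 1

    records = []
    dosage_blocks = []
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        nv = int(per_chrom[ci])
        gaps = rng.integers(1, 2 * config.mean_spacing_bp, size=nv)
        positions = np.cumsum(gaps)
        maf = rng.uniform(*config.maf_range, size=nv)
        rho = np.exp(-gaps[1:] / config.ld_decay_bp)

        latent = np.empty((nv, n_hap))
        latent[0] = rng.standard_normal(n_hap)
        noise = rng.standard_normal((nv - 1, n_hap)) if nv > 1 else np.empty((0, n_hap))
        for k in range(1, nv):
            latent[k] = rho[k - 1] * latent[k - 1] + np.sqrt(1 - rho[k - 1] ** 2) * noise[k - 1]
        thresh = stats.norm.ppf(maf)
        haplo = (latent < thresh[:, None]).astype(np.int8)
        dos = haplo[:, : config.n_samples] + haplo[:, config.n_samples :]
        dosage_blocks.append(dos.astype(float))

        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=nv)
        freq = dos.mean(axis=1) / 2.0
        for k in range(nv):
            oa, ca = _ALLELE_PAIRS[pair_idx[k]]
            records.append(
                dict(
                    variant_id=f"snp_{chrom}_{positions[k]}",
                    chromosome=chrom,
                    position=int(positions[k]),
                    allele_a=oa,
                    allele_b=ca,
                    panel_maf=float(min(freq[k], 1.0 - freq[k])),
                )
            )
    return ReferencePanel(
        variants=pd.DataFrame(records), dosages=np.concatenate(dosage_blocks, axis=0)
    )


def _segment_annotations(
    rng: np.random.Generator,
    panel: ReferencePanel,
    names: list[str],
    coverage: float,
    corr_target: float,
    seg_bp: int,
    category: str = "Synthetic Context",
    source: str = "synthetic",
) -> list[Annotation]:
    share = np.sqrt(np.clip(corr_target, 0.0, 1.0))
    library = []
    # per-chromosome segment grids and a shared template
    grids = {}
    for chrom, grp in panel.variants.groupby("chromosome", sort=False):
        n_seg = int(grp["position"].max()) // seg_bp + 1
        grids[str(chrom)] = (n_seg, rng.random(n_seg) < coverage)
    for name in names:
        intervals = []
        for chrom, (n_seg, template) in grids.items():
            copy = rng.random(n_seg) < share
            own = rng.random(n_seg) < coverage
            on = np.where(copy, template, own)
            # merge consecutive on-segments into intervals
            edges = np.flatnonzero(np.diff(np.concatenate([[0], on.astype(int), [0]])))
            for s, e in zip(edges[::2], edges[1::2]):
                intervals.append((chrom, int(s) * seg_bp, int(e) * seg_bp))
        library.append(Annotation(name=name, category=category, source=source, intervals=intervals))
    return library


def simulate_annotations(
    config: SimConfig, panel: ReferencePanel
) -> tuple[list[Annotation], MembershipMatrix]:
    """Correlated segment-union annotations plus their membership matrix."""
    rng = config.rng(1)
    seg_bp = 2 * config.mean_spacing_bp
    library = _segment_annotations(
        rng,
        panel,
        config.annotation_names(),
        config.annotation_coverage,
        config.annotation_corr_target,
        seg_bp,
    )
    membership = build_membership(panel.variants, library)
    return library, membership


def simulate_baseline(
    config: SimConfig, panel: ReferencePanel
) -> tuple[list[Annotation], MembershipMatrix]:
    """A miniature baseline model: coding-like, conserved-like, broad-regulatory.

    Stands in for the large published baseline annotation sets; columns are
    mutually independent interval draws at three coverage scales.
    """
    rng = config.rng(2)
    seg_bp = 2 * config.mean_spacing_bp
    specs = [("baseline_coding", 0.015), ("baseline_conserved", 0.05), ("baseline_regulatory", 0.3)]
    library: list[Annotation] = []
    for name, cov in specs:
        library += _segment_annotations(
            rng, panel, [name], cov, 0.0, seg_bp, category="Baseline", source="baseline"
        )
    membership = build_membership(panel.variants, library)
    return library, membership


def simulate_sumstats(
    config: SimConfig,
    panel: ReferencePanel,
    membership: MembershipMatrix,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """GWAS summary statistics under the enriched-annotation architecture."""
    rng = config.rng(3)
    M = panel.n_variants
    if membership.variant_ids != list(panel.variants["variant_id"]):
        raise ValueError("membership must be built on the panel variants")

    in_causal = np.zeros(M, dtype=bool)
    for name in config.causal_annotations:
        if name in membership.annotation_names:
            in_causal |= membership.column(name) > 0
    weight = 1.0 + (config.enrichment_fold - 1.0) * in_causal
    per_snp_h2 = (
        weight / weight.sum() * config.h2_total if config.h2_total > 0 else np.zeros(M)
    )

    if config.n_causal_snps == 0 and config.h2_total > 0:
        raise ValueError("h2_total > 0 requires n_causal_snps > 0")

    beta = np.zeros(M)
    causal_idx = np.array([], dtype=int)
    if config.n_causal_snps > 0 and config.h2_total > 0:
        # Bernoulli selection with inclusion probability proportional to
        # per-SNP h2 (capped at 1, scale calibrated so the expected causal
        # count equals n_causal_snps), and conditional effect variance
        # per_snp_h2 / pi: unconditionally E[beta_j^2] = per_snp_h2_j at
        # every polygenicity, so the realized enrichment is unbiased.
        w = per_snp_h2
        target = min(config.n_causal_snps, M)
        lo, hi = 0.0, target / w.sum()
        while np.minimum(hi * w, 1.0).sum() < target and hi < 1e18:
            hi *= 2.0
        for _ in range(200):
            t = 0.5 * (lo + hi)
            if np.minimum(t * w, 1.0).sum() < target:
                lo = t
            else:
                hi = t
        pi = np.minimum(hi * w, 1.0)
        causal_mask = rng.random(M) < pi
        causal_idx = np.where(causal_mask)[0]
        var_cond = per_snp_h2[causal_idx] / pi[causal_idx]
        beta[causal_idx] = rng.standard_normal(causal_idx.size) * np.sqrt(var_cond)

    n_eff = effective_sample_size(config.n_case, config.n_control, "finemap")
    X = panel.standardized()
    chroms = panel.variants["chromosome"].astype(str).to_numpy()
    z = np.zeros(M)
    for chrom in pd.unique(chroms):
        sel = np.where(chroms == chrom)[0]
        Xc = X[sel]
        mean_part = np.zeros(sel.size)
        causal_here = causal_idx[np.isin(causal_idx, sel)]
        if causal_here.size:
            r = (Xc @ X[causal_here].T) / config.n_samples  # (n_chr, n_causal_chr)
            mean_part = r @ beta[causal_here]
        u = rng.standard_normal(config.n_samples)
        eps = (Xc @ u) / np.sqrt(config.n_samples)
        z[sel] = np.sqrt(n_eff) * mean_part + eps

    se = 1.0 / np.sqrt(n_eff)
    pvalue = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    eaf = panel.dosages.mean(axis=1) / 2.0
    records = pd.DataFrame(
        dict(
            variant_id=panel.variants["variant_id"],
            chromosome=chroms,
            position=panel.variants["position"].astype(int),
            effect_allele=panel.variants["allele_b"],
            other_allele=panel.variants["allele_a"],
            eaf=eaf,
            beta=z * se,
            se=se,
            pvalue=pvalue,
            info=1.0,
            n_case=config.n_case,
            n_control=config.n_control,
        )
    )
    truth = SyntheticTruth(
        causal_annotation_names=list(config.causal_annotations),
        causal_variant_ids=[membership.variant_ids[i] for i in causal_idx],
        per_snp_h2=per_snp_h2,
        true_beta=beta,
    )
    return records, truth


def simulate_priors_and_s2g(
    config: SimConfig, truth: SyntheticTruth, variant_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy per-SNP heritability priors and synthetic SNP-gene links.

    Priors are the true per-SNP heritabilities perturbed by multiplicative
    log-normal noise (sd ``prior_noise_sd``).  Each causal variant gets a
    gene link with score in [0.5, 1); an equal number of decoy links on
    non-causal variants score in [0, 0.5).
    """
    rng = config.rng(4)
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(truth.per_snp_h2.size)]
    noise = (
        np.exp(rng.normal(0.0, config.prior_noise_sd, size=truth.per_snp_h2.size))
        if config.prior_noise_sd > 0
        else np.ones(truth.per_snp_h2.size)
    )
    priors = pd.DataFrame(
        dict(variant_id=variant_ids, per_snp_h2=truth.per_snp_h2 * noise)
    )

    links = []
    for vid in truth.causal_variant_ids:
        links.append(dict(variant_id=vid, gene=f"GENE_{vid}", score=rng.uniform(0.5, 1.0)))
    non_causal = [v for v in variant_ids if v not in set(truth.causal_variant_ids)]
    n_decoys = min(len(truth.causal_variant_ids), len(non_causal))
    if n_decoys:
        decoy_ids = rng.choice(len(non_causal), size=n_decoys, replace=False)
        for i in decoy_ids:
            vid = non_causal[int(i)]
            links.append(dict(variant_id=vid, gene=f"GENE_{vid}", score=rng.uniform(0.0, 0.5)))
    s2g = pd.DataFrame(links, columns=["variant_id", "gene", "score"])
    return priors, s2g


def write_inputs(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate all synthetic inputs and write them in the pipeline's formats.

    Produces sumstats.tsv, a BED file + manifest.tsv per-annotation
    library, a panel directory, priors.tsv and s2g.tsv, plus truth.tsv
    listing causal variants.  Returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(config)
    library, membership = simulate_annotations(config, panel)
    baseline_lib, _ = simulate_baseline(config, panel)
    sumstats, truth = simulate_sumstats(config, panel, membership)
    priors, s2g = simulate_priors_and_s2g(
        config, truth, variant_ids=list(panel.variants["variant_id"])
    )

    paths: dict[str, Path] = {}
    panel_dir = outdir / "panel"
    panel.save(panel_dir)
    paths["panel"] = panel_dir

    def write_bed_library(lib: list[Annotation], subdir: str, manifest_name: str) -> Path:
        bed_dir = outdir / subdir
        bed_dir.mkdir(exist_ok=True)
        rows = []
        for ann in lib:
            bed = bed_dir / f"{ann.name}.bed"
            with open(bed, "w") as fh:
                for chrom, s, e in ann.intervals:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
            rows.append(dict(file=bed.name, name=ann.name, category=ann.category, source=ann.source))
        manifest = outdir / manifest_name
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        return manifest

    paths["manifest"] = write_bed_library(library, "annotations", "manifest.tsv")
    paths["baseline_manifest"] = write_bed_library(baseline_lib, "baseline", "baseline_manifest.tsv")
    paths["sumstats"] = outdir / "sumstats.tsv"
    sumstats.to_csv(paths["sumstats"], sep="\t", index=False)
    paths["priors"] = outdir / "priors.tsv"
    priors.to_csv(paths["priors"], sep="\t", index=False)
    paths["s2g"] = outdir / "s2g.tsv"
    s2g.to_csv(paths["s2g"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    pd.DataFrame(
        dict(
            variant_id=list(panel.variants["variant_id"]),
            per_snp_h2=truth.per_snp_h2,
            true_beta=truth.true_beta,
            causal=np.isin(panel.variants["variant_id"], truth.causal_variant_ids).astype(int),
        )
    ).to_csv(paths["truth"], sep="\t", index=False)
    (outdir / "causal_annotations.txt").write_text(
        "\n".join(truth.causal_annotation_names) + "\n"
    )
    paths["causal_annotations"] = outdir / "causal_annotations.txt"
    return paths
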