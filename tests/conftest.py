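"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctfm.simulate import (
    SimConfig,
    simulate_annotations,
    simulate_baseline,
    simulate_panel,
    simulate_sumstats,
)


def make_record(
    variant_id="rs1",
    chromosome="1",
    position=1000,
    effect_allele="A",
    other_allele="C",
    eaf=0.3,
    beta=0.1,
    se=0.1,
    pvalue=0.01,
    info=0.95,
    n_case=1000,
    n_control=1000,
):
    return dict(
        variant_id=variant_id,
        chromosome=chromosome,
        position=position,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        info=info,
        n_case=n_case,
        n_control=n_control,
    )


@pytest.fixture(scope="session")
def qc_fixture():
    """10 records: 3 clean plus violations of six filter classes (the
    multi-allelic site is a two-record event).  Hand-applied expectation:
    survivors {clean1, clean2, clean3}; removals non_autosomal=1,
    multi_allelic=2, strand_ambiguous=1, low_info=1, low_maf=1,
    extreme_beta=1."""
    rows = [
        make_record("clean1", position=1000),
        make_record("clean2", position=2000, effect_allele="G", other_allele="T"),
        make_record("clean3", chromosome="2", position=3500),
        make_record("sexchr", chromosome="X", position=4000),
        make_record("multi_a", chromosome="2", position=9000, effect_allele="A", other_allele="C"),
        make_record("multi_b", chromosome="2", position=9000, effect_allele="A", other_allele="G"),
        make_record("ambig", position=5000, effect_allele="A", other_allele="T"),
        make_record("lowinfo", position=6000, info=0.85),
        make_record("rare", position=7000, eaf=0.001),
        make_record("bigbeta", position=8000, beta=3.5),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated data set shared across read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_variants=2000,
        n_chromosomes=1,
        n_samples=200,
        n_annotations=8,
        n_causal_snps=200,
    )
    panel = simulate_panel(cfg)
    library, membership = simulate_annotations(cfg, panel)
    baseline_lib, baseline = simulate_baseline(cfg, panel)
    sumstats, truth = simulate_sumstats(cfg, panel, membership)
    return dict(
        config=cfg,
        panel=panel,
        library=library,
        membership=membership,
        baseline=baseline,
        sumstats=sumstats,
        truth=truth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def endtoend():
    """Full-scale recovery runs at the generator's default study
    conditions (10^4 variants, 500 samples, 40 annotations, one causal
    annotation at 5-fold enrichment), 20 seeds.  Shared by the module
    recovery tests and the acceptance suite so the heavy computation runs
    once."""
    from ctfm.contexts import run_ctfm
    from ctfm.ldscore import (
        annotation_correlation,
        compute_ld_scores,
        stratified_regression,
    )
    from ctfm.snp_contexts import eligible_variants, run_ctfm_snp
    from ctfm.sumstats import effective_sample_size

    runs = []
    for seed in range(1, 21):
        cfg = SimConfig(seed=seed)
        panel = simulate_panel(cfg)
        _, membership = simulate_annotations(cfg, panel)
        _, baseline = simulate_baseline(cfg, panel)
        sumstats, truth = simulate_sumstats(cfg, panel, membership)
        ld = compute_ld_scores(panel, membership, baseline)
        chisq = ((sumstats["beta"] / sumstats["se"]) ** 2).to_numpy()
        n_eff = effective_sample_size(cfg.n_case, cfg.n_control, "ldsc")
        enrichments = stratified_regression(chisq, ld, n_eff)
        corr = annotation_correlation(ld)
        contexts = run_ctfm(enrichments, corr, cancer="sim")

        causal_name = truth.causal_annotation_names[0]
        vindex = {v: i for i, v in enumerate(membership.variant_ids)}
        cmask = membership.column(causal_name) > 0
        overlapping = [v for v in truth.causal_variant_ids if cmask[vindex[v]]][:25]
        parts = eligible_variants(overlapping, membership, enrichments)
        snp_hits = snp_total = 0
        for vid in parts["tested"]:
            trip = run_ctfm_snp(vid, enrichments, corr, membership, cancer="sim")
            hit = trip.loc[trip["annotation"] == causal_name, "pip"]
            snp_total += 1
            snp_hits += bool(len(hit) and hit.iloc[0] >= 0.5)
        runs.append(
            dict(
                seed=seed,
                causal=causal_name,
                enrichments=enrichments,
                corr=corr,
                contexts=contexts,
                membership=membership,
                truth=truth,
                snp_hits=snp_hits,
                snp_total=snp_total,
            )
        )
    return runs
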