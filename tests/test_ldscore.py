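"""LD scores, stratified regression, jackknife and annotation correlations."""

import numpy as np
import pandas as pd
import pytest

from ctfm.annotations import MembershipMatrix
from ctfm.ldscore import (
    LDScoreMatrix,
    annotation_correlation,
    compute_ld_scores,
    count_significant,
    multiple_testing,
    stratified_regression,
)
from ctfm.simulate import (
    SimConfig,
    simulate_annotations,
    simulate_baseline,
    simulate_panel,
    simulate_sumstats,
)
from ctfm.sumstats import ReferencePanel, effective_sample_size


def _panel(dosages, positions=None, chromosome="1"):
    n = dosages.shape[0]
    positions = positions if positions is not None else (np.arange(n) + 1) * 1000
    freq = dosages.mean(axis=1) / 2
    variants = pd.DataFrame(
        dict(
            variant_id=[f"v{i}" for i in range(n)],
            chromosome=chromosome,
            position=positions,
            allele_a="A",
            allele_b="C",
            panel_maf=np.minimum(freq, 1 - freq),
        )
    )
    return ReferencePanel(variants=variants, dosages=dosages.astype(float))


def _membership(values, names=None):
    values = np.atleast_2d(np.asarray(values))
    return MembershipMatrix(
        values=values.astype(np.int8),
        variant_ids=[f"v{i}" for i in range(values.shape[0])],
        annotation_names=names or [f"a{i}" for i in range(values.shape[1])],
    )


class TestComputeLDScores:
    def test_two_variant_sum_matches_direct_formula(self, rng):
        dos = rng.integers(0, 3, size=(2, 40)).astype(float)
        panel = _panel(dos)
        mem = _membership([[1], [1]])
        ld = compute_ld_scores(panel, mem, None)
        n = 40
        r2 = np.corrcoef(dos)[0, 1] ** 2
        adj = r2 - (1 - r2) / (n - 2)
        # self term is exactly 1 after adjustment
        assert ld.column("a0")[0] == pytest.approx(1.0 + adj, abs=1e-12)

    def test_isolated_variant_has_self_score_one(self, rng):
        dos = rng.integers(0, 3, size=(2, 30)).astype(float)
        panel = _panel(dos, positions=[1000, 5_000_000])
        ld = compute_ld_scores(panel, _membership([[1], [1]]), None, window_bp=10_000)
        np.testing.assert_allclose(ld.column("a0"), 1.0, atol=1e-12)

    def test_empty_annotation_scores_zero(self, rng):
        dos = rng.integers(0, 3, size=(3, 30)).astype(float)
        ld = compute_ld_scores(_panel(dos), _membership([[0], [0], [0]]), None)
        np.testing.assert_allclose(ld.column("a0"), 0.0)

    def test_windowed_equals_brute_force_all_pairs(self, small_sim):
        """With the window spanning the chromosome, scores equal the naive
        all-pairs double sum."""
        panel, mem = small_sim["panel"], small_sim["membership"]
        sub = 300  # keep the O(p^2) oracle cheap
        panel_sub = ReferencePanel(
            variants=panel.variants.iloc[:sub].reset_index(drop=True),
            dosages=panel.dosages[:sub],
        )
        mem_sub = MembershipMatrix(
            values=mem.values[:sub],
            variant_ids=mem.variant_ids[:sub],
            annotation_names=mem.annotation_names,
        )
        span = int(panel_sub.variants["position"].max()) + 1
        ld = compute_ld_scores(panel_sub, mem_sub, None, window_bp=span)
        X = panel_sub.standardized()
        n = panel_sub.n_samples
        r2 = (X @ X.T / n) ** 2
        adj = r2 - (1 - r2) / (n - 2)
        expected = adj @ mem_sub.values.astype(float)
        got = ld.values[:, [ld.column_names.index(a) for a in mem_sub.annotation_names]]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_small_panel_errors(self):
        dos = np.ones((2, 2))
        with pytest.raises(ValueError, match="3 samples"):
            compute_ld_scores(_panel(dos), _membership([[1], [1]]), None)


class TestStratifiedRegression:
    def test_jackknife_nblocks_n_equals_leave_one_out(self, rng):
        """Explicit n_blocks = n_variants reproduces the closed-form
        delete-one jackknife computed by direct matrix algebra."""
        nv = 60
        dos = rng.integers(0, 3, size=(nv, 50)).astype(float)
        panel = _panel(dos)
        mem = _membership(rng.integers(0, 2, size=(nv, 1)))
        ld = compute_ld_scores(panel, mem, None, window_bp=5000)
        chisq = rng.chisquare(1, nv) + 0.5
        res = stratified_regression(chisq, ld, n_eff=100.0, n_blocks=nv, weights="ols")
        # independent closed-form leave-one-out oracle
        cols = [ld.column_names.index("base"), ld.column_names.index("a0")]
        D = np.column_stack([np.ones(nv), 100.0 * ld.values[:, cols]])
        y = chisq - 1
        xtx, xty = D.T @ D, D.T @ y
        deletes = np.array(
            [
                np.linalg.solve(xtx - np.outer(D[i], D[i]), xty - D[i] * y[i])[-1]
                for i in range(nv)
            ]
        )
        se = np.sqrt((nv - 1) / nv * ((deletes - deletes.mean()) ** 2).sum())
        assert res["tau_se"].iloc[0] == pytest.approx(se, rel=1e-10)

    def test_zero_ld_column_flagged_degenerate(self, rng):
        nv = 40
        dos = rng.integers(0, 3, size=(nv, 30)).astype(float)
        mem = _membership(np.zeros((nv, 1), dtype=int))
        ld = compute_ld_scores(_panel(dos), mem, None)
        res = stratified_regression(rng.chisquare(1, nv) + 0.5, ld, n_eff=100.0)
        row = res.iloc[0]
        assert row["degenerate"] and row["tau"] == 0.0 and row["z"] == 0.0

    def test_rank_deficient_design_names_columns(self, rng):
        nv = 40
        values = rng.uniform(1, 2, size=(nv, 1))
        ld = LDScoreMatrix(
            values=np.column_stack([values, values]),  # base duplicated by context
            variant_ids=[f"v{i}" for i in range(nv)],
            column_names=["base", "ctx"],
            baseline_names=[],
            context_names=["ctx"],
            annot=np.column_stack([np.ones(nv), np.ones(nv)]),
            window_bp=0,
        )
        with pytest.raises(ValueError, match="collinear"):
            stratified_regression(
                rng.chisquare(1, nv), ld, n_eff=10.0, weights="ols", fit_intercept=False
            )

    def test_null_architecture_tau_consistent_with_zero(self):
        """Without enrichment the focal coefficient stays within 2 SE of 0
        in nearly all replicates."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=3000 + seed,
                n_variants=2000,
                n_chromosomes=1,
                n_samples=150,
                n_annotations=4,
                enrichment_fold=1.0,
                n_causal_snps=300,
            )
            panel = simulate_panel(cfg)
            _, mem = simulate_annotations(cfg, panel)
            _, bmem = simulate_baseline(cfg, panel)
            ss, _ = simulate_sumstats(cfg, panel, mem)
            ld = compute_ld_scores(panel, mem, bmem)
            chisq = ((ss.beta / ss.se) ** 2).to_numpy()
            n_eff = effective_sample_size(cfg.n_case, cfg.n_control, "ldsc")
            res = stratified_regression(chisq, ld, n_eff)
            row = res[res.annotation == "context_000"].iloc[0]
            hits += abs(row["tau"]) <= 2 * row["tau_se"]
        assert hits / n_rep >= 0.9

    def test_enriched_annotation_attains_top_z(self, endtoend):
        """A single 5x-enriched annotation ranks first by z in most seeds."""
        top = sum(
            run["enrichments"].sort_values("z", ascending=False).iloc[0]["annotation"]
            == run["causal"]
            for run in endtoend
        )
        assert top / len(endtoend) >= 0.8


class TestMultipleTesting:
    def test_bonferroni_and_bh_hand_computed(self):
        df = pd.DataFrame(dict(annotation=list("abc"), p_value=[0.001, 0.02, 0.9]))
        out = multiple_testing(df)
        assert list(out["bonferroni_sig"]) == [True, False, False]
        np.testing.assert_allclose(out["fdr_q"], [0.003, 0.03, 0.9], atol=1e-12)

    def test_all_ones(self):
        df = pd.DataFrame(dict(annotation=list("ab"), p_value=[1.0, 1.0]))
        out = multiple_testing(df)
        assert not out["bonferroni_sig"].any()
        np.testing.assert_allclose(out["fdr_q"], 1.0)

    def test_single_test_identity(self):
        out = multiple_testing(pd.DataFrame(dict(annotation=["a"], p_value=[0.04])))
        assert bool(out["bonferroni_sig"].iloc[0])
        assert out["fdr_q"].iloc[0] == pytest.approx(0.04)


def _corr_ld(target: np.ndarray, n_rows: int = 500, seed: int = 5) -> LDScoreMatrix:
    """LD-score matrix whose context columns have exactly the target
    sample correlation after demeaning (constructed via Cholesky on
    orthonormalized noise)."""
    k = target.shape[0]
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_rows, k))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    ctx = q @ np.linalg.cholesky(target).T
    values = np.column_stack([np.ones(n_rows), ctx])
    return LDScoreMatrix(
        values=values,
        variant_ids=[f"v{i}" for i in range(n_rows)],
        column_names=["base"] + [f"c{i}" for i in range(k)],
        baseline_names=[],
        context_names=[f"c{i}" for i in range(k)],
        annot=np.ones_like(values),
        window_bp=0,
    )


class TestAnnotationCorrelation:
    def test_identical_columns_correlate_one(self):
        ld = _corr_ld(np.eye(2))
        ld.values[:, 2] = ld.values[:, 1]
        corr = annotation_correlation(ld)
        assert corr.matrix[0, 1] == pytest.approx(1.0)

    def test_column_equal_to_baseline_flagged_degenerate(self, rng):
        n = 200
        base = rng.uniform(1, 3, n)
        values = np.column_stack([base, 2.0 * base + 1.0, rng.normal(size=n)])
        ld = LDScoreMatrix(
            values=values,
            variant_ids=[f"v{i}" for i in range(n)],
            column_names=["base", "c0", "c1"],
            baseline_names=[],
            context_names=["c0", "c1"],
            annot=np.ones_like(values),
            window_bp=0,
        )
        corr = annotation_correlation(ld)
        assert corr.degenerate == ["c0"]
        assert np.isnan(corr.matrix[0, 1])

    def test_mean_abs_offdiag_from_known_correlations(self):
        target = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, -0.1], [0.2, -0.1, 1.0]])
        corr = annotation_correlation(_corr_ld(target))
        np.testing.assert_allclose(corr.matrix, target, atol=1e-8)
        assert corr.mean_abs_offdiag == pytest.approx((0.5 + 0.2 + 0.1) / 3, abs=1e-8)

    def test_invariant_to_affine_rescaling(self):
        target = np.array([[1.0, 0.3], [0.3, 1.0]])
        ld = _corr_ld(target)
        before = annotation_correlation(ld).matrix.copy()
        ld.values[:, 1] = 5.0 * ld.values[:, 1] - 2.0
        after = annotation_correlation(ld).matrix
        np.testing.assert_allclose(before, after, atol=1e-10)

    def test_matrix_is_symmetric_unit_diagonal(self, small_sim):
        from ctfm.ldscore import compute_ld_scores

        ld = compute_ld_scores(small_sim["panel"], small_sim["membership"], small_sim["baseline"])
        corr = annotation_correlation(ld)
        assert np.allclose(corr.matrix, corr.matrix.T, atol=1e-10)
        assert np.allclose(np.diag(corr.matrix), 1.0)
        assert np.nanmax(np.abs(corr.matrix)) <= 1.0 + 1e-12


def test_count_significant_totals():
    frames = {
        c: pd.DataFrame(dict(fdr_q=[0.01] * n + [0.5] * 3))
        for c, n in [("a", 2), ("b", 4)]
    }
    out = count_significant(frames)
    assert out.set_index("cancer")["n_significant"].to_dict() == {"a": 2, "b": 4, "total": 6}
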