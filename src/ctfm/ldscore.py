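"""Stratified LD-score regression (S-LDSC) for heritability enrichment.

For variant j and annotation c the LD score is

    l(j, c) = sum_{k in window(j)} a_c(k) * r2_adj(j, k)

with the small-sample adjustment ``r2_adj = r2 - (1 - r2)/(n - 2)`` applied
to squared correlations estimated from a reference panel.  S-LDSC fits

    E[chi2_j] = 1 + n_eff * (tau_c * l(j, c) + sum_b tau_b * l(j, b))

one focal context annotation c at a time jointly with a fixed set of
baseline columns (a "marginal" enrichment scan: fitting all ~10^3 contexts
jointly is both unstable and unnecessary for scoring).  Standard errors
come from a leave-one-block-out jackknife over contiguous, equal-count
variant blocks; the enrichment z-score defaults to the jackknife z of the
focal coefficient tau_c conditional on baseline.

The correlation matrix of baseline-adjusted context LD scores — each
context column residualized on the baseline columns — is the matrix that
context fine-mapping (CT-FM) consumes in place of variant LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ctfm.annotations import MembershipMatrix
from ctfm.sumstats import ReferencePanel


@dataclass
class LDScoreMatrix:
    """Annotation-stratified LD scores plus the matching indicators.

    Columns are ordered: ``base`` (all-ones annotation), baseline columns,
    then context columns.  ``annot`` holds the 0/1 indicator of each column
    on the same variant rows, needed to turn coefficients into enrichment.
    """

    values: np.ndarray  # (n_variants, n_columns)
    variant_ids: list[str]
    column_names: list[str]
    baseline_names: list[str]
    context_names: list[str]
    annot: np.ndarray  # (n_variants, n_columns) indicators
    window_bp: int

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    def design_columns(self, focal: str) -> list[str]:
        return ["base", *self.baseline_names, focal]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "variant_id", self.variant_ids)
        return df


@dataclass
class AnnotationCorrelation:
    """Correlations of baseline-adjusted context LD scores."""

    matrix: np.ndarray  # (n_contexts, n_contexts), unit diagonal
    names: list[str]
    mean_abs_offdiag: float
    degenerate: list[str] = field(default_factory=list)

    def submatrix(self, names: list[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.matrix[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)


def compute_ld_scores(
    panel: ReferencePanel,
    membership: MembershipMatrix,
    baseline: MembershipMatrix | None = None,
    window_bp: int = 1_000_000,
    chunk: int = 512,
) -> LDScoreMatrix:
    """Windowed annotation-stratified LD scores from a reference panel.

    Correlations are computed between standardized dosages; pairs beyond
    ``window_bp`` of each other (or on different chromosomes) contribute
    zero.  The self term is included (adjusted r2 of a variant with itself
    is exactly 1).  Rows and neighbor sums run over the membership
    variants, which must be a subset of the panel.
    """
    n = panel.n_samples
    if n < 3:
        raise ValueError("panel must have at least 3 samples for the r2 adjustment")
    if baseline is not None and baseline.variant_ids != membership.variant_ids:
        raise ValueError("baseline and membership must cover the same variants in order")

    panel_idx = {v: i for i, v in enumerate(panel.variants["variant_id"])}
    try:
        rows = np.array([panel_idx[v] for v in membership.variant_ids])
    except KeyError as e:
        raise ValueError(f"membership variant missing from panel: {e.args[0]}") from None

    baseline_names = list(baseline.annotation_names) if baseline is not None else []
    context_names = list(membership.annotation_names)
    column_names = ["base", *baseline_names, *context_names]
    m = len(membership.variant_ids)
    blocks = [np.ones((m, 1), dtype=float)]
    if baseline is not None:
        blocks.append(baseline.values.astype(float))
    blocks.append(membership.values.astype(float))
    A = np.concatenate(blocks, axis=1)  # (m, n_cols)

    X = panel.standardized()[rows]  # (m, n_samples)
    chroms = panel.variants["chromosome"].astype(str).to_numpy()[rows]
    pos = panel.variants["position"].to_numpy()[rows]

    values = np.zeros((m, A.shape[1]))
    for chrom in pd.unique(chroms):
        sel = np.where(chroms == chrom)[0]
        order = sel[np.argsort(pos[sel], kind="stable")]
        cp = pos[order]
        cx = X[order]
        ca = A[order]
        lo = np.searchsorted(cp, cp - window_bp, side="left")
        hi = np.searchsorted(cp, cp + window_bp, side="right")
        out = np.zeros((order.size, A.shape[1]))
        for start in range(0, order.size, chunk):
            stop = min(start + chunk, order.size)
            k0, k1 = lo[start:stop].min(), hi[start:stop].max()
            r = (cx[start:stop] @ cx[k0:k1].T) / n
            r2 = r**2
            adj = r2 - (1.0 - r2) / (n - 2)
            cols = np.arange(k0, k1)
            mask = (cols >= lo[start:stop, None]) & (cols < hi[start:stop, None])
            out[start:stop] = (adj * mask) @ ca[k0:k1]
        values[order] = out

    return LDScoreMatrix(
        values=values,
        variant_ids=list(membership.variant_ids),
        column_names=column_names,
        baseline_names=baseline_names,
        context_names=context_names,
        annot=A,
        window_bp=window_bp,
    )


def _collinear_columns(D: np.ndarray, names: list[str]) -> list[str]:
    _, s, vt = np.linalg.svd(D, full_matrices=False)
    null = vt[-1]
    return [names[i] for i in np.where(np.abs(null) > 1e-6)[0]]


def _ldsc_weights(ld: LDScoreMatrix, chisq: np.ndarray, n_eff: float) -> np.ndarray:
    """Heteroskedasticity + overcounting weights in the LDSC style.

    Var(chi2_j) is approximately 2*(1 + n_eff*h2*l_tot_j/M)^2 under the
    polygenic model; dividing additionally by the (floored) total LD score
    downweights variants whose chi2 is tagged by many regression SNPs.
    The aggregate h2 estimate used inside the weights comes from the
    method-of-moments relation mean(chi2) = 1 + n_eff*h2*mean(l)/M.
    """
    l_tot = np.maximum(ld.column("base"), 1.0)
    M = ld.n_variants
    h2_agg = (chisq.mean() - 1.0) * M / (n_eff * l_tot.mean())
    h2_agg = float(np.clip(h2_agg, 0.0, 1.0))
    het = 2.0 * (1.0 + n_eff * h2_agg * l_tot / M) ** 2
    return 1.0 / (het * l_tot)


def stratified_regression(
    chisq: np.ndarray,
    ld: LDScoreMatrix,
    n_eff: float,
    n_blocks: int | None = None,
    weights: str = "ldsc",
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Marginal S-LDSC scan: one focal context at a time with baseline.

    Returns one row per context column with the focal coefficient ``tau``,
    its block-jackknife standard error, ``z = tau/tau_se``, the enrichment
    statistic (share of h2 in the annotation over its share of variants)
    with its own jackknife SE, and a two-sided normal p-value.  Context
    columns with no members or an all-zero LD score are flagged
    ``degenerate`` with tau = z = 0.

    ``fit_intercept`` (default, the standard S-LDSC behavior) estimates a
    free regression intercept that absorbs uniform chi-squared inflation
    from confounding or attenuated LD; with ``False`` the intercept is
    pinned at 1.
    """
    chisq = np.asarray(chisq, dtype=float).ravel()
    nv = ld.n_variants
    if chisq.size != nv:
        raise ValueError("chisq length does not match LD score rows")
    if n_blocks is None:
        # the S-LDSC convention of 200 blocks, shrunk on small fixtures
        n_blocks_eff = max(2, min(200, nv // 10))
    else:
        if n_blocks > nv:
            raise ValueError(f"n_blocks={n_blocks} exceeds n_variants={nv}")
        n_blocks_eff = max(2, n_blocks)

    if weights == "ldsc":
        w = _ldsc_weights(ld, chisq, n_eff)
    elif weights == "ols":
        w = np.ones(nv)
    else:
        raise ValueError(f"unknown weights: {weights!r}")
    sw = np.sqrt(w)

    y = chisq - 1.0
    block_ids = np.repeat(np.arange(n_blocks_eff), np.diff(np.linspace(0, nv, n_blocks_eff + 1).astype(int)))

    name_to_col = {n: i for i, n in enumerate(ld.column_names)}
    base_cols = [name_to_col[c] for c in ["base", *ld.baseline_names]]

    rows = []
    for focal in ld.context_names:
        fcol = name_to_col[focal]
        a_focal = ld.annot[:, fcol]
        m_focal = float(a_focal.sum())
        prop = m_focal / nv
        if m_focal == 0 or not np.any(ld.values[:, fcol]):
            rows.append(
                dict(
                    annotation=focal,
                    tau=0.0,
                    tau_se=np.nan,
                    z=0.0,
                    enrichment=np.nan,
                    enrichment_se=np.nan,
                    prop_snps=prop,
                    p_value=1.0,
                    degenerate=True,
                )
            )
            continue
        cols = base_cols + [fcol]
        D = n_eff * ld.values[:, cols]
        if fit_intercept:
            D = np.column_stack([np.ones(nv), D])
        Dw = D * sw[:, None]
        yw = y * sw
        if np.linalg.matrix_rank(Dw) < Dw.shape[1]:
            names = (["intercept"] if fit_intercept else []) + ld.design_columns(focal)
            raise ValueError(f"rank-deficient design for {focal!r}; collinear columns: "
                             f"{_collinear_columns(Dw, names)}")

        # per-block weighted moments, so delete-one estimates are O(k^2)
        k = D.shape[1]
        xtx_b = np.zeros((n_blocks_eff, k, k))
        xty_b = np.zeros((n_blocks_eff, k))
        for b in range(n_blocks_eff):
            sel = block_ids == b
            xtx_b[b] = Dw[sel].T @ Dw[sel]
            xty_b[b] = Dw[sel].T @ yw[sel]
        xtx = xtx_b.sum(axis=0)
        xty = xty_b.sum(axis=0)
        theta = np.linalg.solve(xtx, xty)

        annot_sub = ld.annot[:, cols]  # (nv, n_annot_cols)
        offset = 1 if fit_intercept else 0

        def enrich(t: np.ndarray) -> float:
            per_snp = annot_sub @ t[offset:]
            h2_tot = float(per_snp.sum())
            h2_c = float(per_snp[a_focal > 0].sum())
            if h2_tot == 0:
                return np.nan
            return (h2_c / h2_tot) / prop

        deletes = np.zeros((n_blocks_eff, k))
        enrich_del = np.zeros(n_blocks_eff)
        for b in range(n_blocks_eff):
            tb = np.linalg.solve(xtx - xtx_b[b], xty - xty_b[b])
            deletes[b] = tb
            enrich_del[b] = enrich(tb)
        jk_mean = deletes.mean(axis=0)
        tau_se = float(
            np.sqrt((n_blocks_eff - 1) / n_blocks_eff * ((deletes[:, -1] - jk_mean[-1]) ** 2).sum())
        )
        e_hat = enrich(theta)
        e_mean = np.nanmean(enrich_del)
        e_se = float(
            np.sqrt(
                (n_blocks_eff - 1)
                / n_blocks_eff
                * np.nansum((enrich_del - e_mean) ** 2)
            )
        )
        tau = float(theta[-1])
        z = tau / tau_se if tau_se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            dict(
                annotation=focal,
                tau=tau,
                tau_se=tau_se,
                z=z,
                enrichment=e_hat,
                enrichment_se=e_se,
                prop_snps=prop,
                p_value=p,
                degenerate=False,
            )
        )
    return pd.DataFrame(rows)


def multiple_testing(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni flags and Benjamini-Hochberg q-values over one cancer's scan."""
    out = results.copy()
    p = out["p_value"].to_numpy()
    m = len(p)
    out["bonferroni_sig"] = p <= alpha / m if m else []
    if m:
        _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        out["fdr_q"] = q
    else:
        out["fdr_q"] = []
    return out


def count_significant(
    results_by_cancer: dict[str, pd.DataFrame],
    criterion: str = "fdr",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cancer counts of significant annotations plus a grand total.

    ``criterion`` is ``"fdr"`` (rows with ``fdr_q <= alpha``) or
    ``"bonferroni"`` (rows flagged ``bonferroni_sig``).
    """
    rows = []
    total = 0
    for cancer, df in results_by_cancer.items():
        if criterion == "fdr":
            n = int((df["fdr_q"] <= alpha).sum())
        elif criterion == "bonferroni":
            n = int(df["bonferroni_sig"].sum())
        else:
            raise ValueError(f"unknown criterion: {criterion!r}")
        rows.append({"cancer": cancer, "n_significant": n})
        total += n
    rows.append({"cancer": "total", "n_significant": total})
    return pd.DataFrame(rows)


def annotation_correlation(ld: LDScoreMatrix) -> AnnotationCorrelation:
    """Pearson correlations of context LD scores residualized on baseline.

    Each context column is regressed (OLS with intercept) on the base and
    baseline columns; the correlation matrix of the residuals is what
    context fine-mapping uses in place of variant LD.  Residual columns
    with zero variance are flagged degenerate: their correlations are NaN
    and they are excluded from ``mean_abs_offdiag``.
    """
    name_to_col = {n: i for i, n in enumerate(ld.column_names)}
    base = ld.values[:, [name_to_col[c] for c in ["base", *ld.baseline_names]]]
    design = np.column_stack([np.ones(ld.n_variants), base])
    ctx = ld.values[:, [name_to_col[c] for c in ld.context_names]]
    coef, *_ = np.linalg.lstsq(design, ctx, rcond=None)
    resid = ctx - design @ coef

    sd = resid.std(axis=0)
    scale = max(float(np.abs(ctx).max()), 1.0)
    ok = sd > 1e-12 * scale
    k = len(ld.context_names)
    matrix = np.full((k, k), np.nan)
    if ok.sum() >= 1:
        sub = np.corrcoef(resid[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        matrix[np.ix_(np.where(ok)[0], np.where(ok)[0])] = sub
    matrix = np.clip(matrix, -1.0, 1.0)
    matrix = 0.5 * (matrix + matrix.T)
    np.fill_diagonal(matrix, 1.0)

    off = matrix[~np.eye(k, dtype=bool)]
    defined = off[~np.isnan(off)]
    mean_abs = float(np.abs(defined).mean()) if defined.size else 0.0
    return AnnotationCorrelation(
        matrix=matrix,
        names=list(ld.context_names),
        mean_abs_offdiag=mean_abs,
        degenerate=[n for n, good in zip(ld.context_names, ok) if not good],
    )
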