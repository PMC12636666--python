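"""Genome-wide context fine-mapping (CT-FM).

Takes the S-LDSC enrichment scan and the correlation matrix of
baseline-adjusted annotation LD scores, restricts to annotations with
positive enrichment z-scores, and fine-maps them with the SuSiE engine as
if the z-scores were association statistics and the LD-score correlations
were LD.  Contexts are tiered by PIP: high-confidence (>= 0.5), candidate
(0.05 <= PIP < 0.5), or none.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ctfm.ldscore import AnnotationCorrelation
from ctfm.susie import FineMapProblem, fit_susie_rss

PIP_HIGH = 0.5
PIP_CANDIDATE = 0.05


def _tier(pip: float, pip_high: float = PIP_HIGH, pip_candidate: float = PIP_CANDIDATE) -> str:
    if pip >= pip_high:
        return "high_confidence"
    if pip >= pip_candidate:
        return "candidate"
    return "none"


def run_ctfm(
    enrichments: pd.DataFrame,
    corr: AnnotationCorrelation,
    L: int = 10,
    coverage: float = 0.95,
    purity: float | str = "auto",
    cancer: str = "",
) -> pd.DataFrame:
    """Fine-map positively enriched annotations genome-wide.

    Only annotations with z > 0 (and a well-defined correlation row) enter
    the SuSiE problem with uniform priors; every other annotation is
    reported with pip = 0 and tier ``none`` so downstream joins are total.
    ``purity="auto"`` uses the library-wide mean absolute off-diagonal
    correlation as the credible-set purity threshold.

    Returns a table with columns cancer, annotation, sldsc_z, pip,
    credible_set_id, credible_set_size, tier.
    """
    purity_min = corr.mean_abs_offdiag if purity == "auto" else float(purity)

    enr = enrichments.set_index("annotation")
    usable = [
        n
        for n in corr.names
        if n in enr.index
        and enr.loc[n, "z"] > 0
        and not bool(enr.loc[n].get("degenerate", False))
        and n not in corr.degenerate
    ]
    if len(usable) < 2:
        warnings.warn("fewer than 2 positive-z annotations; nothing to fine-map")
        return pd.DataFrame(
            columns=[
                "cancer",
                "annotation",
                "sldsc_z",
                "pip",
                "credible_set_id",
                "credible_set_size",
                "tier",
            ]
        )

    z = enr.loc[usable, "z"].to_numpy(dtype=float)
    R = corr.submatrix(usable)
    problem = FineMapProblem(z=z, R=R, L=L, coverage=coverage, purity_min=purity_min)
    fit = fit_susie_rss(problem)

    set_id = {}
    set_size = {}
    for i, cs in enumerate(fit.credible_sets):
        for j in cs.members:
            set_id[usable[j]] = i
            set_size[usable[j]] = len(cs.members)

    rows = []
    pip_by_name = dict(zip(usable, fit.pip))
    for name in enr.index:
        pip = float(pip_by_name.get(name, 0.0))
        rows.append(
            dict(
                cancer=cancer,
                annotation=name,
                sldsc_z=float(enr.loc[name, "z"]),
                pip=pip,
                credible_set_id=set_id.get(name, pd.NA),
                credible_set_size=set_size.get(name, pd.NA),
                tier=_tier(pip),
            )
        )
    return pd.DataFrame(rows)


def classify_contexts(results: pd.DataFrame) -> pd.DataFrame:
    """Count contexts per cancer and tier (high_confidence / candidate / none)."""
    if results.empty:
        return pd.DataFrame(columns=["cancer", "tier", "count"])
    out = (
        results.groupby(["cancer", "tier"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out
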