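"""{regulatory SNP, context, gene, cancer} quadruplet construction.

Joins high-confidence SNP-context triplets (CT-FM-SNP PIP >= 0.5) with
high-confidence SNP-gene links (cS2G-style score >= 0.5) on the variant,
producing one quadruplet per qualifying (context, gene) combination.  A
reporting helper keeps, for each (cancer, variant, gene) pair, the context
with the highest PIP.
"""

from __future__ import annotations

import pandas as pd


def join_quadruplets(
    triplets: pd.DataFrame,
    links: pd.DataFrame,
    pip_min: float = 0.5,
    s2g_min: float = 0.5,
) -> pd.DataFrame:
    """Cartesian join of qualifying triplets and SNP-gene links per variant.

    ``triplets`` needs columns variant_id, annotation, cancer, pip;
    ``links`` needs variant_id, gene, score.  Rows are ordered by
    (cancer, variant, gene, descending pip) for determinism.
    """
    t = triplets.loc[triplets["pip"] >= pip_min, ["variant_id", "annotation", "cancer", "pip"]]
    s = links.loc[links["score"] >= s2g_min, ["variant_id", "gene", "score"]]
    out = t.merge(s, on="variant_id", how="inner")
    out = out.rename(columns={"pip": "context_pip", "score": "s2g_score"})
    out = out.sort_values(
        ["cancer", "variant_id", "gene", "context_pip", "annotation"],
        ascending=[True, True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return out[["cancer", "variant_id", "annotation", "gene", "context_pip", "s2g_score"]]


def best_context_per_pair(quads: pd.DataFrame) -> pd.DataFrame:
    """One row per (cancer, variant, gene): the context with maximal PIP.

    Exact PIP ties are broken alphabetically by context name.
    """
    if quads.empty:
        return quads.copy()
    df = quads.sort_values(
        ["cancer", "variant_id", "gene", "context_pip", "annotation"],
        ascending=[True, True, True, False, True],
        kind="stable",
    )
    return df.drop_duplicates(["cancer", "variant_id", "gene"], keep="first").reset_index(
        drop=True
    )
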