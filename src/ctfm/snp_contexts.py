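"""Variant-level context fine-mapping (CT-FM-SNP).

For each high-confidence causal variant, the annotations overlapping it
that carry a positive genome-wide enrichment z-score form a restricted
SuSiE problem (their z-scores against the corresponding block of the
annotation correlation matrix).  Variants overlapping fewer than two such
annotations are reported but not fine-mapped.  The output is one
{variant, context, cancer} triplet per annotation in the restricted
problem, carrying its variant-specific PIP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ctfm.annotations import MembershipMatrix
from ctfm.ldscore import AnnotationCorrelation
from ctfm.susie import FineMapProblem, fit_susie_rss

PIP_HIGH = 0.5


def _positive_overlaps(
    variant_id: str,
    membership: MembershipMatrix,
    enrichments: pd.DataFrame,
    corr: AnnotationCorrelation | None = None,
) -> list[str]:
    row = membership.values[membership.variant_ids.index(variant_id)]
    enr = enrichments.set_index("annotation")
    names = []
    for name, inside in zip(membership.annotation_names, row):
        if not inside or name not in enr.index:
            continue
        if enr.loc[name, "z"] <= 0 or bool(enr.loc[name].get("degenerate", False)):
            continue
        if corr is not None and name in corr.degenerate:
            continue
        names.append(name)
    return names


def eligible_variants(
    causal: pd.DataFrame | list[str],
    membership: MembershipMatrix,
    enrichments: pd.DataFrame,
) -> dict[str, list[str]]:
    """Partition causal variants by their positive-z annotation overlap.

    Returns ``{"tested": [...], "single_overlap": [...], "zero_overlap":
    [...]}``: variants overlapping >= 2 positive-z annotations are tested
    by CT-FM-SNP, those with exactly one are reported but not fine-mapped,
    the rest overlap nothing informative.
    """
    ids = list(causal["variant_id"]) if isinstance(causal, pd.DataFrame) else list(causal)
    out: dict[str, list[str]] = {"tested": [], "single_overlap": [], "zero_overlap": []}
    for vid in ids:
        k = len(_positive_overlaps(vid, membership, enrichments))
        if k >= 2:
            out["tested"].append(vid)
        elif k == 1:
            out["single_overlap"].append(vid)
        else:
            out["zero_overlap"].append(vid)
    return out


def run_ctfm_snp(
    variant_id: str,
    enrichments: pd.DataFrame,
    corr: AnnotationCorrelation,
    membership: MembershipMatrix,
    L: int = 10,
    coverage: float = 0.95,
    purity: float | str = "auto",
    cancer: str = "",
) -> pd.DataFrame:
    """Fine-map the contexts overlapping one variant.

    The purity threshold reuses the library-wide mean absolute
    off-diagonal correlation (per-variant sub-matrices are too small for a
    stable local average), and L is capped at the number of restricted
    annotations.  Annotation pairs that are perfectly correlated in the
    restricted block are collapsed to one representative; the duplicates
    are emitted with NaN PIP and a ``duplicate_of`` pointer.
    """
    names = _positive_overlaps(variant_id, membership, enrichments, corr)
    if len(names) < 2:
        raise ValueError(
            f"variant {variant_id!r} overlaps {len(names)} positive-z annotation(s); "
            "CT-FM-SNP requires at least 2"
        )
    enr = enrichments.set_index("annotation")
    R = corr.submatrix(names)

    # collapse |corr| == 1 duplicates to a representative
    rep: dict[int, int] = {}
    for i in range(len(names)):
        for j in range(i):
            if abs(abs(R[i, j]) - 1.0) < 1e-9 and j in _roots(rep, range(len(names))):
                rep[i] = _root(rep, j)
                break
    keep = [i for i in range(len(names)) if i not in rep]
    z = np.array([float(enr.loc[names[i], "z"]) for i in keep])
    Rk = R[np.ix_(keep, keep)]
    purity_min = corr.mean_abs_offdiag if purity == "auto" else float(purity)
    problem = FineMapProblem(
        z=z, R=Rk, L=min(L, len(keep)), coverage=coverage, purity_min=purity_min
    )
    fit = fit_susie_rss(problem)

    set_id = {}
    for s, cs in enumerate(fit.credible_sets):
        for j in cs.members:
            set_id[keep[j]] = s

    pip_by_idx = {keep[j]: float(fit.pip[j]) for j in range(len(keep))}
    rows = []
    for i, name in enumerate(names):
        dup_of = names[_root(rep, i)] if i in rep else pd.NA
        rows.append(
            dict(
                variant_id=variant_id,
                annotation=name,
                cancer=cancer,
                pip=pip_by_idx.get(i, np.nan),
                n_overlapping=len(names),
                credible_set_id=set_id.get(i, pd.NA),
                duplicate_of=dup_of,
            )
        )
    return pd.DataFrame(rows)


def _root(rep: dict[int, int], i: int) -> int:
    while i in rep:
        i = rep[i]
    return i


def _roots(rep: dict[int, int], idx) -> set[int]:
    return {_root(rep, i) for i in idx}


def summarize_contexts(triplets: pd.DataFrame, pip_min: float = PIP_HIGH) -> pd.DataFrame:
    """Per-context counts of variants where it is high-confidence.

    Returns a table sorted by descending count with ``most_frequent``
    recorded in ``attrs``; when every context is detected for only one
    variant, no single context can be called most frequent and the label
    is ``"*"``.
    """
    if triplets.empty:
        out = pd.DataFrame(columns=["annotation", "n_variants"])
        out.attrs["most_frequent"] = None
        return out
    high = triplets[triplets["pip"] >= pip_min]
    if high.empty:
        out = pd.DataFrame(columns=["annotation", "n_variants"])
        out.attrs["most_frequent"] = None
        return out
    counts = (
        high.groupby("annotation")["variant_id"]
        .nunique()
        .rename("n_variants")
        .reset_index()
        .sort_values(["n_variants", "annotation"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    top = counts.iloc[0]
    counts.attrs["most_frequent"] = "*" if top["n_variants"] <= 1 else str(top["annotation"])
    return counts
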