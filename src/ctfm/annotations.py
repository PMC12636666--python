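"""Annotation library: named genomic interval sets and variant membership.

Each annotation is a named collection of intervals marking candidate
cis-regulatory elements active in one biological context (a primary cell
type, a cell line, or bulk tumor tissue), carrying free-text ``category``
and ``source`` metadata from the library manifest.  Intervals follow the
BED convention: 0-based, half-open ``[start, end)``.  GWAS positions are
1-based, so a variant at position ``p`` falls in an interval iff
``start <= p - 1 < end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of intervals per chromosome; adjacent runs are coalesced."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    for chrom in sorted(by_chrom):
        runs = sorted(by_chrom[chrom])
        cur_s, cur_e = runs[0]
        for s, e in runs[1:]:
            if s <= cur_e:  # overlapping or adjacent
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


@dataclass
class Annotation:
    """A named interval set with category/source metadata.

    ``intervals`` are normalized on construction: merged per chromosome,
    sorted, non-overlapping, 0-based half-open.
    """

    name: str
    category: str
    source: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(
                    f"annotation {self.name!r}: invalid interval ({chrom}, {start}, {end})"
                )
        if self.intervals:
            self.intervals = _merge_intervals(self.intervals)

    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chromosome: str, position: int) -> bool:
        """Membership of a 1-based variant position."""
        q = position - 1
        for chrom, start, end in self.intervals:
            if chrom == str(chromosome) and start <= q < end:
                return True
        return False


@dataclass
class MembershipMatrix:
    """Binary variant-by-annotation indicator matrix."""

    values: np.ndarray  # (n_variants, n_annotations), {0,1}
    variant_ids: list[str]
    annotation_names: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.annotation_names.index(name)]

    def prop_snps(self) -> np.ndarray:
        """Per-annotation share of variants covered."""
        return self.values.mean(axis=0)

    def to_triplets(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "variant_id": [self.variant_ids[r] for r in rows],
                "annotation": [self.annotation_names[c] for c in cols],
                "value": np.ones(len(rows), dtype=int),
            }
        )


def load_annotation_library(
    paths: list[str | Path],
    manifest: pd.DataFrame,
) -> list[Annotation]:
    """Load BED3+ files into annotations ordered by the manifest.

    ``manifest`` must contain columns ``file``, ``name``, ``category``,
    ``source``; ``paths`` are resolved against the manifest by file name.
    Extra BED columns are ignored.  Empty BED files produce an annotation
    with zero intervals (with a warning).
    """
    required = {"file", "name", "category", "source"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(manifest.columns))}")
    by_name = {Path(p).name: Path(p) for p in paths}
    seen: set[str] = set()
    library: list[Annotation] = []
    for _, row in manifest.iterrows():
        fname = Path(row["file"]).name
        if row["name"] in seen:
            raise ValueError(f"duplicate annotation name: {row['name']!r}")
        seen.add(row["name"])
        path = by_name.get(fname)
        if path is None:
            raise FileNotFoundError(f"manifest references {fname} but no such path was given")
        intervals: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{fname}:{lineno}: fewer than 3 BED columns")
                chrom = fields[0].removeprefix("chr")
                start, end = int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(f"{fname}:{lineno}: start >= end ({start} >= {end})")
                intervals.append((chrom, start, end))
        if not intervals:
            warnings.warn(f"annotation {row['name']!r}: empty BED file {fname}")
        library.append(
            Annotation(
                name=row["name"],
                category=row["category"],
                source=row["source"],
                intervals=intervals,
            )
        )
    return library


def build_membership(variants: pd.DataFrame, library: list[Annotation]) -> MembershipMatrix:
    """Indicator matrix: entry (j, c) = 1 iff variant j lies in annotation c.

    Uses binary search over each annotation's merged, sorted intervals.
    """
    n = len(variants)
    values = np.zeros((n, len(library)), dtype=np.int8)
    chroms = variants["chromosome"].astype(str).to_numpy()
    pos0 = variants["position"].to_numpy().astype(np.int64) - 1  # to 0-based

    for c, ann in enumerate(library):
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, start, end in ann.intervals:
            by_chrom.setdefault(chrom, ([], []))  # type: ignore[arg-type]
        for chrom in by_chrom:
            runs = [(s, e) for ch, s, e in ann.intervals if ch == chrom]
            starts = np.array([s for s, _ in runs], dtype=np.int64)
            ends = np.array([e for _, e in runs], dtype=np.int64)
            by_chrom[chrom] = (starts, ends)
        for chrom, (starts, ends) in by_chrom.items():
            sel = np.where(chroms == chrom)[0]
            if sel.size == 0:
                continue
            q = pos0[sel]
            k = np.searchsorted(starts, q, side="right") - 1
            ok = k >= 0
            inside = np.zeros(sel.size, dtype=bool)
            inside[ok] = q[ok] < ends[k[ok]]
            values[sel[inside], c] = 1
    return MembershipMatrix(
        values=values,
        variant_ids=list(variants["variant_id"]),
        annotation_names=[a.name for a in library],
    )


def subset_library(
    library: list[Annotation],
    exclude_source: str | None = None,
    exclude_names: list[str] | None = None,
) -> list[Annotation]:
    """Remove annotations by source and/or explicit name, preserving order."""
    exclude_names = set(exclude_names or [])
    matched_names = {a.name for a in library if a.name in exclude_names}
    unmatched = exclude_names - matched_names
    if unmatched:
        warnings.warn(f"exclusion names not in library: {sorted(unmatched)}")
    kept = [
        a
        for a in library
        if not ((exclude_source is not None and a.source == exclude_source) or a.name in exclude_names)
    ]
    if exclude_source is not None and len(kept) == len(library) and not matched_names:
        warnings.warn(f"no annotation with source {exclude_source!r}")
    return kept


def library_manifest(library: list[Annotation]) -> pd.DataFrame:
    """Per-source and per-category counts plus a grand total.

    Returns a tidy table with columns ``kind`` (source/category/total),
    ``label`` and ``count``.
    """
    rows: list[dict] = []
    by_source: dict[str, int] = {}
    by_category: dict[str, int] = {}
    for a in library:
        by_source[a.source] = by_source.get(a.source, 0) + 1
        by_category[a.category] = by_category.get(a.category, 0) + 1
    for label, count in sorted(by_source.items()):
        rows.append({"kind": "source", "label": label, "count": count})
    for label, count in sorted(by_category.items()):
        rows.append({"kind": "category", "label": label, "count": count})
    rows.append({"kind": "total", "label": "total", "count": len(library)})
    return pd.DataFrame(rows, columns=["kind", "label", "count"])
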