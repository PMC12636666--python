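"""GWAS summary-statistics ingestion, quality control and panel harmonization.

Summary statistics live in a :class:`pandas.DataFrame` with one row per
variant and the canonical columns

    variant_id, chromosome, position, effect_allele, other_allele,
    eaf, beta, se, pvalue, info, n_case, n_control

where ``beta`` is the log-odds effect of ``effect_allele``, ``eaf`` its
frequency, and ``info`` the imputation quality (NaN when the study did not
report one).  QC removes sex-chromosome variants, multi-allelic sites,
strand-ambiguous allele pairs (A/T, C/G), poorly imputed or rare variants,
extreme effects, invalid p-values and duplicated physical positions, in
that fixed order, attributing each removal to the first failing filter so
accounting is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "info",
    "n_case",
    "n_control",
]

#: columns that must be present and parseable for a row to be kept
MANDATORY = [c for c in CANONICAL_COLUMNS if c != "info"]

_NUMERIC = ["position", "eaf", "beta", "se", "pvalue", "info", "n_case", "n_control"]
_INT = ["position", "n_case", "n_control"]

AUTOSOMES = {str(i) for i in range(1, 23)}

#: strand-ambiguous allele pairs — indistinguishable between strands
AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

#: filter application order; attribution is to the first failing filter
QC_FILTER_ORDER = [
    "non_autosomal",
    "multi_allelic",
    "strand_ambiguous",
    "low_info",
    "low_maf",
    "extreme_beta",
    "invalid_pvalue",
    "duplicate_position",
]


@dataclass
class QCReport:
    """Bookkeeping for a sequential filtering pass.

    ``n_input - n_output == sum(counts_removed.values())`` whenever each
    removed row is attributed to exactly one filter.
    """

    n_input: int
    n_output: int
    counts_removed: dict[str, int] = field(default_factory=dict)
    notes: dict[str, int] = field(default_factory=dict)

    def total_removed(self) -> int:
        return sum(self.counts_removed.values())

    def to_text(self) -> str:
        lines = [f"n_input\t{self.n_input}", f"n_output\t{self.n_output}"]
        lines += [f"removed.{k}\t{v}" for k, v in self.counts_removed.items()]
        lines += [f"note.{k}\t{v}" for k, v in self.notes.items()]
        return "\n".join(lines) + "\n"


@dataclass
class ReferencePanel:
    """Genotype reference panel for LD computation.

    Attributes
    ----------
    variants : DataFrame with columns variant_id, chromosome, position,
        allele_a, allele_b, panel_maf.  ``allele_b`` is the counted allele:
        the dosage of variant *i* in sample *s* is the number of copies of
        ``allele_b`` (in [0, 2]).  Positions must be strictly increasing
        within each chromosome.
    dosages : float array, variants x samples.
    """

    variants: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.shape[0] != len(self.variants):
            raise ValueError("dosage rows do not match variant table")
        for chrom, grp in self.variants.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"panel positions not strictly sorted on chromosome {chrom}")
        maf = self.maf_from_dosages()
        if not np.allclose(maf, self.variants["panel_maf"].to_numpy(), atol=1e-9):
            raise ValueError("panel_maf inconsistent with dosages")

    def maf_from_dosages(self) -> np.ndarray:
        freq = self.dosages.mean(axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def standardized(self) -> np.ndarray:
        """Dosages standardized to mean 0, variance 1 per variant."""
        x = self.dosages.astype(float)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        sd[sd == 0] = 1.0
        return x / sd[:, None]

    # -- plain-text persistence -------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(directory / "variants.tsv", sep="\t", index=False)
        np.savetxt(directory / "dosages.tsv", self.dosages, fmt="%.6g", delimiter="\t")

    @classmethod
    def load(cls, directory: str | Path) -> "ReferencePanel":
        directory = Path(directory)
        variants = pd.read_csv(directory / "variants.tsv", sep="\t", dtype={"chromosome": str})
        dosages = np.loadtxt(directory / "dosages.tsv", delimiter="\t", ndmin=2)
        return cls(variants=variants, dosages=dosages)


def _normalize_chromosome(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip()
    return s.str.replace(r"^chr", "", regex=True, case=False)


def read_sumstats(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics table into canonical form.

    Parameters
    ----------
    path : delimited text file with a header row.
    dialect : optional mapping from file column names to canonical names,
        e.g. ``{"CHR": "chromosome", "BP": "position"}``.  Canonical names
        already present pass through unchanged.
    sep : field separator; sniffed from the header (tab, then comma) when
        omitted.

    Rows whose mandatory fields are missing or unparseable are dropped and
    counted in ``df.attrs["n_unparseable"]``; missing INFO values are kept
    as NaN and treated as passing the INFO filter downstream.

    Raises
    ------
    ValueError
        If a mandatory column is absent after applying the dialect, or the
        file is empty.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty summary-statistics file: {path}")
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] == 0):
        raise ValueError(f"empty summary-statistics file: {path}")
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if "info" not in df.columns:
        df["info"] = np.nan

    df = df[CANONICAL_COLUMNS].copy()
    n_raw = len(df)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = np.ones(n_raw, dtype=bool)
    for col in MANDATORY:
        ok &= df[col].notna().to_numpy()
    n_unparseable = int((~ok).sum())
    if n_unparseable:
        warnings.warn(f"dropped {n_unparseable} unparseable row(s) from {path.name}")
    df = df.loc[ok].reset_index(drop=True)
    for col in _INT:
        df[col] = df[col].astype(int)
    df["chromosome"] = _normalize_chromosome(df["chromosome"])
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    df.attrs["n_unparseable"] = n_unparseable
    return df


def apply_qc_filters(
    records: pd.DataFrame,
    info_min: float = 0.9,
    maf_min: float = 0.005,
    beta_max: float = 3.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the fixed-order QC filter cascade.

    Order (each removal attributed to the first failing filter):
    non-autosomal -> multi-allelic -> strand-ambiguous -> INFO < ``info_min``
    (missing INFO passes) -> MAF < ``maf_min`` -> ``|beta| > beta_max`` ->
    invalid p-value -> residual duplicated physical positions (every record
    at a duplicated (chromosome, position) is dropped).
    """
    df = records.copy().reset_index(drop=True)
    n_input = len(df)
    counts: dict[str, int] = {}
    notes = {"missing_info": int(df["info"].isna().sum())}

    def drop(mask: np.ndarray, name: str, frame: pd.DataFrame) -> pd.DataFrame:
        counts[name] = int(mask.sum())
        return frame.loc[~mask].reset_index(drop=True)

    chrom = _normalize_chromosome(df["chromosome"])
    df = drop(~chrom.isin(AUTOSOMES).to_numpy(), "non_autosomal", df)

    # multi-allelic: same physical position under >1 variant_id, or >2
    # distinct alleles across its rows
    grp = df.groupby(["chromosome", "position"])
    n_ids = grp["variant_id"].transform("nunique").to_numpy()
    allele_sets = grp.apply(
        lambda g: len(set(g["effect_allele"]) | set(g["other_allele"])),
        include_groups=False,
    )
    n_alleles = (
        df.set_index(["chromosome", "position"]).index.map(allele_sets).to_numpy()
        if len(df)
        else np.array([], dtype=int)
    )
    df = drop((n_ids > 1) | (n_alleles > 2), "multi_allelic", df)

    pairs = [frozenset((a, b)) for a, b in zip(df["effect_allele"], df["other_allele"])]
    df = drop(np.array([p in AMBIGUOUS_PAIRS for p in pairs], dtype=bool), "strand_ambiguous", df)

    info = df["info"].to_numpy()
    df = drop((~np.isnan(info)) & (info < info_min), "low_info", df)

    maf = np.minimum(df["eaf"].to_numpy(), 1.0 - df["eaf"].to_numpy())
    df = drop(maf < maf_min, "low_maf", df)

    df = drop(np.abs(df["beta"].to_numpy()) > beta_max, "extreme_beta", df)

    p = df["pvalue"].to_numpy()
    df = drop((p <= 0) | (p > 1), "invalid_pvalue", df)

    dup = df.duplicated(["chromosome", "position"], keep=False).to_numpy()
    df = drop(dup, "duplicate_position", df)

    report = QCReport(n_input=n_input, n_output=len(df), counts_removed=counts, notes=notes)
    return df, report


def align_to_reference(
    records: pd.DataFrame,
    panel: ReferencePanel,
    maf_diff_max: float = 0.2,
    panel_maf_min: float = 0.005,
) -> tuple[pd.DataFrame, QCReport]:
    """Harmonize QC-passed records against a reference panel.

    A record is kept when a panel variant at the same (chromosome, position)
    carries the same unordered allele pair.  When the GWAS effect allele is
    the panel's ``allele_a`` (i.e. orientation is swapped relative to the
    counted allele), ``beta`` is negated and ``eaf`` replaced by ``1-eaf``
    so that effects are always expressed for the panel's counted allele.
    Records whose panel MAF is below ``panel_maf_min`` or whose GWAS/panel
    MAF difference exceeds ``maf_diff_max`` are dropped.
    """
    for chrom, grp in panel.variants.groupby("chromosome", sort=False):
        if not np.all(np.diff(grp["position"].to_numpy()) > 0):
            raise ValueError(f"reference panel unsorted on chromosome {chrom}")

    pv = panel.variants
    key = pd.MultiIndex.from_arrays(
        [pv["chromosome"].astype(str), pv["position"].astype(int)]
    )
    lookup = pd.Series(np.arange(len(pv)), index=key)

    df = records.copy().reset_index(drop=True)
    n_input = len(df)
    counts = {"absent_from_panel": 0, "allele_mismatch": 0, "panel_low_maf": 0, "maf_discrepancy": 0}

    rec_key = pd.MultiIndex.from_arrays(
        [df["chromosome"].astype(str), df["position"].astype(int)]
    )
    idx = lookup.reindex(rec_key)
    present = idx.notna().to_numpy()
    counts["absent_from_panel"] = int((~present).sum())
    df = df.loc[present].reset_index(drop=True)
    pidx = idx.to_numpy()[present].astype(int)

    aa = pv["allele_a"].to_numpy()[pidx]
    ab = pv["allele_b"].to_numpy()[pidx]
    ea = df["effect_allele"].to_numpy()
    oa = df["other_allele"].to_numpy()
    aligned = (ea == ab) & (oa == aa)
    swapped = (ea == aa) & (oa == ab)
    match = aligned | swapped
    counts["allele_mismatch"] = int((~match).sum())
    df, pidx, aligned, swapped = (
        df.loc[match].reset_index(drop=True),
        pidx[match],
        aligned[match],
        swapped[match],
    )

    pmaf = pv["panel_maf"].to_numpy()[pidx]
    low = pmaf < panel_maf_min
    counts["panel_low_maf"] = int(low.sum())
    df, pidx, pmaf, swapped = (
        df.loc[~low].reset_index(drop=True),
        pidx[~low],
        pmaf[~low],
        swapped[~low],
    )

    gmaf = np.minimum(df["eaf"].to_numpy(), 1.0 - df["eaf"].to_numpy())
    disc = np.abs(gmaf - pmaf) > maf_diff_max
    counts["maf_discrepancy"] = int(disc.sum())
    df, swapped = df.loc[~disc].reset_index(drop=True), swapped[~disc]

    if swapped.any():
        sw = np.where(swapped)[0]
        df.loc[sw, "beta"] = -df.loc[sw, "beta"]
        df.loc[sw, "eaf"] = 1.0 - df.loc[sw, "eaf"]

    report = QCReport(n_input=n_input, n_output=len(df), counts_removed=counts)
    return df, report


def effective_sample_size(n_case: int, n_control: int, convention: str = "finemap") -> float:
    """Effective sample size of a case-control GWAS.

    ``ldsc`` convention: ``1/(1/Ncase + 1/Ncontrol)`` (used when regressing
    chi-squared statistics on LD scores).  ``finemap`` convention:
    ``4/(1/Ncase + 1/Ncontrol)`` (the usual GWAS effective N, used for
    fine-mapping).  The two differ by an exact factor of 4.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    harmonic = 1.0 / (1.0 / n_case + 1.0 / n_control)
    if convention == "ldsc":
        return harmonic
    if convention == "finemap":
        return 4.0 * harmonic
    raise ValueError(f"unknown convention: {convention!r}")
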