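"""Reading, validation, harmonization, and writing of GWAS/QTL summary statistics.

Summary statistics are carried as a :class:`SummaryStats` — a pandas DataFrame
with fixed column names plus trait metadata. Per-variant allele alignment and
palindromic-variant exclusion live here because every downstream stage
(conjunctional FDR, colocalization, Mendelian randomization) assumes effect
estimates expressed on a common effect allele.

Coordinates are 1-based inclusive for variant positions; interval outputs
(BED) are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: strand-ambiguous (palindromic) allele pairs
PALINDROMIC_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class SumstatsError(ValueError):
    """Raised for unrecoverable summary-statistics problems."""


class AlleleMismatchError(SumstatsError):
    """Allele sets cannot be reconciled, even after strand complement."""

    def __init__(self, record_alleles, ref_alleles):
        self.record_alleles = tuple(record_alleles)
        self.ref_alleles = tuple(ref_alleles)
        super().__init__(
            f"irreconcilable alleles: record {self.record_alleles} "
            f"vs reference {self.ref_alleles}"
        )


@dataclass(frozen=True)
class VariantRecord:
    """One per-variant association estimate.

    ``beta`` is the effect of ``effect_allele`` (log-OR for binary traits,
    SD units for quantitative traits); ``eaf`` may be NaN when unavailable.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float

    def __post_init__(self):
        if self.se <= 0:
            raise SumstatsError(f"{self.variant_id}: nonpositive SE {self.se}")
        if not (0 < self.p <= 1):
            raise SumstatsError(f"{self.variant_id}: p outside (0,1]: {self.p}")
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.variant_id}: identical alleles")
        if self.pos < 1:
            raise SumstatsError(f"{self.variant_id}: position < 1")


@dataclass
class SummaryStats:
    """Association records for one trait in one sex stratum.

    ``df`` holds :data:`COLUMNS`; variant IDs are unique and rows are sorted
    by (chrom, pos).
    """

    df: pd.DataFrame
    trait_label: str = ""
    sex_stratum: str = "combined"
    build_label: str = "synthetic"

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dupes = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise SumstatsError(
                f"duplicate variant IDs: {sorted(set(dupes))[:5]}"
            )
        self.df = (
            self.df[COLUMNS]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[VariantRecord]:
        for row in self.df.itertuples(index=False):
            yield VariantRecord(*row)

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("variant_id", drop=False)


_DROP_REASONS = {
    "se": "nonpositive SE",
    "p": "p outside (0,1]",
    "alleles": "identical alleles",
    "pos": "position < 1",
    "eaf": "eaf outside (0,1)",
    "missing": "missing required value",
}


def read_column_map(path: str | Path) -> dict[str, str]:
    """Load a canonical-name -> file-column mapping from a YAML file.

    Example: ``p: PVAL`` maps the file's PVAL header onto the canonical p
    column.
    """
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    unknown = [k for k in mapping if k not in COLUMNS]
    if unknown:
        raise SumstatsError(f"unknown canonical columns in map: {unknown}")
    return {str(k): str(v) for k, v in mapping.items()}


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    sex_stratum: str = "combined",
    build_label: str = "unknown",
) -> SummaryStats:
    """Load a delimited summary-statistics file, enforcing record invariants.

    ``column_map`` maps canonical names (:data:`COLUMNS`) to the file's
    header names; identity mapping by default. Rows violating invariants are
    dropped and counted in the log; duplicate variant IDs and empty results
    are fatal.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python")
    column_map = dict(column_map or {})
    rename = {}
    for canonical in COLUMNS:
        src = column_map.get(canonical, canonical)
        if src not in raw.columns:
            if canonical == "eaf":
                raw["eaf"] = np.nan
                continue
            raise SumstatsError(
                f"{path}: mandatory column {canonical!r} "
                f"(file column {src!r}) not found"
            )
        rename[src] = canonical
    df = raw.rename(columns=rename)[COLUMNS].copy()

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    dropped: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            dropped[reason] = dropped.get(reason, 0) + k
            df = df[~mask]

    _drop(df[["pos", "beta", "se", "p", "n"]].isna().any(axis=1), _DROP_REASONS["missing"])
    _drop(df["se"] <= 0, _DROP_REASONS["se"])
    _drop(~((df["p"] > 0) & (df["p"] <= 1)), _DROP_REASONS["p"])
    _drop(df["effect_allele"] == df["other_allele"], _DROP_REASONS["alleles"])
    _drop(df["pos"] < 1, _DROP_REASONS["pos"])
    _drop(df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)), _DROP_REASONS["eaf"])

    if df["variant_id"].duplicated().any():
        dupes = sorted(set(df.loc[df["variant_id"].duplicated(), "variant_id"]))
        raise SumstatsError(f"{path}: duplicate variant IDs {dupes[:5]}")
    if len(df) == 0:
        raise SumstatsError(f"{path}: zero valid rows after filtering")

    df["pos"] = df["pos"].astype(int)
    log.info(
        "loaded %s: %d kept, dropped %s",
        path,
        len(df),
        dropped or "none",
    )
    return SummaryStats(
        df.reset_index(drop=True),
        trait_label=trait_label,
        sex_stratum=sex_stratum,
        build_label=build_label,
    )


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write a SummaryStats as tab-delimited text with a header row."""
    stats.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _complement_allele(a: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in a)


def align_to_reference(
    record: VariantRecord, ref_effect: str, ref_other: str
) -> VariantRecord:
    """Express a record's effect on a given reference effect allele.

    Strand-complement matching is attempted before swap detection; a swap
    negates beta and replaces eaf with 1-eaf. Aligning an already-aligned
    record is the identity, so the operation is idempotent.
    """
    ref_effect, ref_other = ref_effect.upper(), ref_other.upper()
    ea, oa = record.effect_allele.upper(), record.other_allele.upper()

    if {ea, oa} != {ref_effect, ref_other}:
        cea, coa = _complement_allele(ea), _complement_allele(oa)
        if {cea, coa} == {ref_effect, ref_other}:
            ea, oa = cea, coa
        else:
            raise AlleleMismatchError((ea, oa), (ref_effect, ref_other))

    if ea == ref_effect and oa == ref_other:
        return replace(record, effect_allele=ea, other_allele=oa)
    # alleles swapped relative to the reference orientation
    eaf = 1.0 - record.eaf if np.isfinite(record.eaf) else record.eaf
    return replace(
        record,
        effect_allele=ref_effect,
        other_allele=ref_other,
        beta=-record.beta,
        eaf=eaf,
    )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous A/T and C/G single-nucleotide pairs."""
    return frozenset({effect_allele.upper(), other_allele.upper()}) in PALINDROMIC_PAIRS


def drop_ambiguous(stats: SummaryStats) -> SummaryStats:
    """Remove palindromic (A/T, C/G) variants.

    Frequency-based rescue of palindromic variants is deliberately not
    attempted; ambiguous variants are always excluded.
    """
    mask = [
        is_palindromic(ea, oa)
        for ea, oa in zip(stats.df["effect_allele"], stats.df["other_allele"])
    ]
    mask = np.asarray(mask, dtype=bool)
    n_removed = int(mask.sum())
    if n_removed:
        log.info("dropped %d palindromic variants", n_removed)
    out = stats.df[~mask].reset_index(drop=True)
    if len(out) == 0:
        log.warning("all variants were palindromic; result is empty")
    result = SummaryStats.__new__(SummaryStats)
    result.df = out
    result.trait_label = stats.trait_label
    result.sex_stratum = stats.sex_stratum
    result.build_label = stats.build_label
    return result


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r-squared) for an ordered variant set."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise SumstatsError(f"LD matrix shape {self.r.shape} != ({m},{m})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise SumstatsError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise SumstatsError("LD matrix diagonal not 1")

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self) -> np.ndarray:
        return self.r**2
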