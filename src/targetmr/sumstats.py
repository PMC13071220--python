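"""GWAS summary-statistics data model, I/O and allele harmonisation.

Tables are tab-separated with a header row; the documented dialect has
columns ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta,
se, pvalue, n`` with the literal string ``NA`` marking a missing ``eaf`` or
``n``.  Positions are 1-based and inclusive throughout.  Only biallelic
SNVs are modelled: indels and multi-allelic records are excluded at read
time, since both the palindrome logic and LD handling are defined for
single-nucleotide variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError

SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one GWAS trait.

    ``scale`` is ``continuous`` for quantitative traits (betas in trait
    units, e.g. mmol/mol for HbA1c) or ``log_odds`` for binary traits.
    ``stratum`` records the sex stratum the GWAS was run in.
    """

    trait_id: str
    trait_name: str
    scale: str
    units: str
    stratum: str = "overall"
    sample_size: int = 0
    n_cases: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scale not in ("continuous", "log_odds"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.stratum not in ("overall", "female", "male"):
            raise ValidationError(f"unknown stratum {self.stratum!r}")
        if self.sample_size <= 0:
            raise ValidationError("sample_size must be positive")
        if self.scale == "log_odds":
            if self.n_cases is None:
                raise ValidationError("binary traits require n_cases")
            if not 0 < self.n_cases < self.sample_size:
                raise ValidationError("require 0 < n_cases < sample_size")


@dataclass(frozen=True)
class SummaryStatRow:
    """One variant's association record for a single trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[float] = None


@dataclass
class SummaryStatTable:
    """A trait's per-variant records plus any rows rejected at read time.

    ``df`` holds one row per variant with the dialect columns; ``invalid``
    lists ``(variant_id, reason)`` for rows that failed validation — they
    are reported, never silently dropped.
    """

    meta: TraitMeta
    df: pd.DataFrame
    invalid: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate variant_id {dup.iloc[0]!r}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.df["variant_id"])

    def row(self, variant_id: str) -> SummaryStatRow:
        sub = self.df[self.df["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return _row_from_record(sub.iloc[0])

    def rows(self) -> Iterable[SummaryStatRow]:
        for _, rec in self.df.iterrows():
            yield _row_from_record(rec)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatTable":
        ids = set(variant_ids)
        sub = self.df[self.df["variant_id"].isin(ids)].reset_index(drop=True)
        return SummaryStatTable(meta=self.meta, df=sub, invalid=[])

    def per_variant_n(self) -> pd.Series:
        """Per-variant sample size, falling back to the trait-level N."""
        return self.df["n"].fillna(float(self.meta.sample_size))


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates; ``tss`` is the 1-based transcription start site."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValidationError(f"tss must be >= 1 for {self.gene_id}")


@dataclass(frozen=True)
class HarmonisedPair:
    """Exposure/outcome effects for one variant on a common effect allele."""

    variant_id: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    p_exposure: float
    p_outcome: float
    palindromic: bool = False
    flipped_outcome: bool = False
    strand_flipped: bool = False


@dataclass
class HarmonisedSet:
    """Aligned exposure/outcome pairs ready for MR, plus dropped variants."""

    exposure_meta: TraitMeta
    outcome_meta: TraitMeta
    pairs: list[HarmonisedPair] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_exposure, se_exposure, beta_outcome, se_outcome)."""
        bx = np.array([p.beta_exposure for p in self.pairs], dtype=float)
        sx = np.array([p.se_exposure for p in self.pairs], dtype=float)
        by = np.array([p.beta_outcome for p in self.pairs], dtype=float)
        sy = np.array([p.se_outcome for p in self.pairs], dtype=float)
        return bx, sx, by, sy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])


@dataclass(frozen=True)
class PalindromePolicy:
    """How to treat A/T and C/G variants whose strand is unresolvable.

    Palindromic variants are dropped when either side's effect-allele
    frequency is missing or when ``min(eaf, 1-eaf) > maf_ambiguity`` on
    either side; otherwise they are aligned by frequency concordance
    (both frequencies on the same side of 0.5).  ``drop_all`` discards
    every palindromic variant regardless of frequency.
    """

    maf_ambiguity: float = 0.42
    drop_all: bool = False


def f_statistic(beta: float, se: float) -> float:
    """Approximated instrument-strength F statistic, ``(beta/se)**2``.

    F > 10 is the conventional weak-instrument screen.
    """
    if np.any(np.asarray(se) <= 0):
        raise DomainError("se must be positive")
    return (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2


def flip_orientation(row: SummaryStatRow) -> SummaryStatRow:
    """Swap effect/other alleles, negating beta and complementing eaf."""
    return replace(
        row,
        effect_allele=row.other_allele,
        other_allele=row.effect_allele,
        beta=-row.beta,
        eaf=None if row.eaf is None else 1.0 - row.eaf,
    )


def _row_from_record(rec) -> SummaryStatRow:
    eaf = rec["eaf"]
    n = rec["n"]
    return SummaryStatRow(
        variant_id=str(rec["variant_id"]),
        chrom=str(rec["chrom"]),
        pos=int(rec["pos"]),
        effect_allele=str(rec["effect_allele"]),
        other_allele=str(rec["other_allele"]),
        beta=float(rec["beta"]),
        se=float(rec["se"]),
        pvalue=float(rec["pvalue"]),
        eaf=None if pd.isna(eaf) else float(eaf),
        n=None if pd.isna(n) else float(n),
    )


def _validate_record(rec) -> Optional[str]:
    """Reason the record is invalid, or None if it passes every invariant."""
    ea = str(rec["effect_allele"]).upper()
    oa = str(rec["other_allele"]).upper()
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        return "non-SNV"
    if ea == oa:
        return "identical alleles"
    try:
        pos = int(rec["pos"])
    except (TypeError, ValueError):
        return "non-integer pos"
    if pos < 1:
        return "nonpositive pos"
    if pd.isna(rec["beta"]):
        return "missing beta"
    if pd.isna(rec["se"]) or float(rec["se"]) <= 0:
        return "nonpositive se"
    p = rec["pvalue"]
    if pd.isna(p) or not 0 < float(p) <= 1:
        return "pvalue out of range"
    eaf = rec["eaf"]
    if not pd.isna(eaf) and not 0 < float(eaf) < 1:
        return "eaf out of range"
    return None


def build_table(meta: TraitMeta, df: pd.DataFrame) -> SummaryStatTable:
    """Validate a raw dialect DataFrame into a SummaryStatTable."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[SUMSTAT_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    invalid: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, rec) in enumerate(df.iterrows()):
        reason = _validate_record(rec)
        if reason is not None:
            invalid.append((str(rec["variant_id"]), reason))
            keep[i] = False
    valid = df[keep].reset_index(drop=True)
    valid["pos"] = valid["pos"].astype(int)
    return SummaryStatTable(meta=meta, df=valid, invalid=invalid)


def read_sumstats(path: str | Path, meta: TraitMeta) -> SummaryStatTable:
    """Read a dialect TSV into a validated table.

    Rows violating per-row invariants are collected in ``table.invalid``
    with a reason; a missing column raises :class:`FormatError` and a
    duplicated variant ID raises :class:`ValidationError`.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str, "chrom": str},
        na_values=["NA"], keep_default_na=True,
    )
    return build_table(meta, df)


def write_sumstats(table: SummaryStatTable, path: str | Path) -> None:
    """Write a table in the dialect; missing eaf/n serialised as ``NA``."""
    out = table.df[SUMSTAT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a tab-separated ``gene_id, symbol, chrom, tss`` table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("gene_id", "symbol", "chrom", "tss") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return [
        GeneAnnotation(str(r.gene_id), str(r.symbol), str(r.chrom), int(r.tss))
        for r in df.itertuples()
    ]


def write_gene_annotations(genes: list[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.symbol, g.chrom, g.tss) for g in genes],
        columns=["gene_id", "symbol", "chrom", "tss"],
    ).to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC_PAIRS


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def harmonise(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    policy: PalindromePolicy = PalindromePolicy(),
) -> HarmonisedSet:
    """Align outcome effects to the exposure's effect allele per variant.

    Variants present in both tables are reconciled by direct allele match,
    allele swap (outcome beta negated), strand complement, or complement
    plus swap; palindromic variants are resolved per ``policy``.  Variants
    whose alleles cannot be reconciled land in ``dropped`` with reason
    ``"allele mismatch"``.  Zero shared variants yields an empty set and a
    warning rather than an exception.
    """
    hs = HarmonisedSet(exposure_meta=exposure.meta, outcome_meta=outcome.meta)
    out_idx = outcome.df.set_index("variant_id")
    shared = [v for v in exposure.df["variant_id"] if v in out_idx.index]
    if not shared:
        warnings.warn(
            "exposure and outcome share no variants; harmonised set is empty",
            stacklevel=2,
        )
        return hs

    exp_idx = exposure.df.set_index("variant_id")
    for vid in shared:
        ex = exp_idx.loc[vid]
        ou = out_idx.loc[vid]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = ou["effect_allele"], ou["other_allele"]
        palindromic = _is_palindromic(ea_x, oa_x)

        if palindromic:
            if {ea_y, oa_y} != {ea_x, oa_x}:
                hs.dropped.append((vid, "allele mismatch"))
                continue
            if policy.drop_all:
                hs.dropped.append((vid, "palindromic dropped by policy"))
                continue
            eaf_x, eaf_y = ex["eaf"], ou["eaf"]
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                hs.dropped.append((vid, "palindromic ambiguous"))
                continue
            if (
                min(eaf_x, 1 - eaf_x) > policy.maf_ambiguity
                or min(eaf_y, 1 - eaf_y) > policy.maf_ambiguity
            ):
                hs.dropped.append((vid, "palindromic ambiguous"))
                continue
            # Align by frequency concordance: the outcome's effect allele is
            # taken to be the exposure's when both frequencies fall on the
            # same side of 0.5.
            flipped = (eaf_x < 0.5) != (eaf_y < 0.5)
            strand_flipped = False
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                flipped, strand_flipped = False, False
            elif (ea_y, oa_y) == (oa_x, ea_x):
                flipped, strand_flipped = True, False
            elif (_complement(ea_y), _complement(oa_y)) == (ea_x, oa_x):
                flipped, strand_flipped = False, True
            elif (_complement(ea_y), _complement(oa_y)) == (oa_x, ea_x):
                flipped, strand_flipped = True, True
            else:
                hs.dropped.append((vid, "allele mismatch"))
                continue

        beta_out = float(ou["beta"])
        if flipped:
            beta_out = -beta_out
        hs.pairs.append(
            HarmonisedPair(
                variant_id=vid,
                effect_allele=str(ea_x),
                beta_exposure=float(ex["beta"]),
                se_exposure=float(ex["se"]),
                beta_outcome=beta_out,
                se_outcome=float(ou["se"]),
                p_exposure=float(ex["pvalue"]),
                p_outcome=float(ou["pvalue"]),
                palindromic=palindromic,
                flipped_outcome=flipped,
                strand_flipped=strand_flipped,
            )
        )
    return hs
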