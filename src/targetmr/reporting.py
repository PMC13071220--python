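"""Analysis orchestration, effect-scale conversion, FDR and result tables.

Estimators return log odds ratios per 1-unit *increase* of the exposure;
this layer alone converts them to odds ratios per unit *decrease*
(mirroring the pharmacological framing of a glucose-lowering drug), so the
sign flip happens in exactly one place.  Multiple-testing correction is
Benjamini–Hochberg at alpha = 0.05, applied separately to the primary and
secondary outcome families over main estimates only; sensitivity-analysis
rows are reported uncorrected and flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .instrument_selection import InstrumentSet, SelectionThresholds
from .mr_estimators import Z_95, MRResult, ivw, run_sensitivity_suite, wald_ratio
from .sumstats import (
    HarmonisedSet,
    PalindromePolicy,
    SummaryStatTable,
    harmonise,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome GWAS in the plan.

    ``sex`` is the outcome's own sex restriction (``overall`` for
    non-sex-specific cancers); ``family`` assigns the FDR family.
    """

    name: str
    table: SummaryStatTable
    family: str = "primary"

    @property
    def sex(self) -> str:
        return self.table.meta.stratum


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure stratum: its instrument set and full summary table."""

    label: str
    stratum: str
    instruments: InstrumentSet
    table: SummaryStatTable


@dataclass
class AnalysisPlan:
    """Exposure/outcome pairing and analysis settings.

    Sex-specific outcomes are analysed with the matching sex-specific
    exposure only; non-sex-specific outcomes are analysed against the
    overall and both sex-specific exposures.
    """

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    palindrome_policy: PalindromePolicy = field(default_factory=PalindromePolicy)
    fdr_alpha: float = 0.05
    n_boot: int = 1000
    seed: Optional[int] = None
    phi: float = 1.0

    def pairings(self) -> list[tuple[ExposureSpec, OutcomeSpec]]:
        out = []
        for outcome in self.outcomes:
            for exposure in self.exposures:
                if outcome.sex == "overall" or exposure.stratum == outcome.sex:
                    out.append((exposure, outcome))
        return out


RESULT_COLUMNS = [
    "exposure", "gene_id", "stratum", "outcome", "family", "method", "is_main",
    "status", "n_snps", "beta", "se", "or_decrease", "or_ci_low", "or_ci_high",
    "pvalue", "fdr_adjusted_p", "fdr_discovery", "q", "q_df", "q_pvalue",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p",
]


@dataclass
class ResultRow:
    """One estimator's result for one exposure/stratum/outcome triple."""

    exposure: str
    gene_id: str
    stratum: str
    outcome: str
    family: str
    method: str
    is_main: bool
    status: str
    n_snps: int = 0
    beta: float = float("nan")
    se: float = float("nan")
    or_decrease: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")
    pvalue: float = float("nan")
    fdr_adjusted_p: float = float("nan")
    fdr_discovery: bool = False
    q: float = float("nan")
    q_df: float = float("nan")
    q_pvalue: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_p: float = float("nan")


def or_per_unit_decrease(beta: float, se: float) -> tuple[float, float, float]:
    """Convert a log odds ratio per unit increase to an OR per unit decrease.

    Returns ``(exp(-beta), ci_low, ci_high)`` with the 95% bounds ordered
    ascending.
    """
    if se <= 0:
        raise DomainError("se must be positive")
    or_dec = float(np.exp(-beta))
    lo = float(np.exp(-beta - Z_95 * se))
    hi = float(np.exp(-beta + Z_95 * se))
    return or_dec, min(lo, hi), max(lo, hi)


def or_per_unit_increase(beta: float, se: float) -> tuple[float, float, float]:
    if se <= 0:
        raise DomainError("se must be positive")
    or_inc = float(np.exp(beta))
    lo = float(np.exp(beta - Z_95 * se))
    hi = float(np.exp(beta + Z_95 * se))
    return or_inc, min(lo, hi), max(lo, hi)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and discovery flags.

    Adjusted values are monotone-enforced and capped at 1; a flag is set
    when the adjusted p-value is at or below ``alpha``.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted <= alpha


def _result_row_from_mr(
    exposure: ExposureSpec,
    gene_id: str,
    outcome: OutcomeSpec,
    res: MRResult,
    is_main: bool,
) -> ResultRow:
    or_dec, lo, hi = (
        or_per_unit_decrease(res.beta, res.se)
        if np.isfinite(res.se) and res.se > 0
        else (float("nan"),) * 3
    )
    return ResultRow(
        exposure=exposure.label,
        gene_id=gene_id,
        stratum=exposure.stratum,
        outcome=outcome.name,
        family=outcome.family,
        method=res.method,
        is_main=is_main,
        status="estimated",
        n_snps=res.n_snps,
        beta=res.beta,
        se=res.se,
        or_decrease=or_dec,
        or_ci_low=lo,
        or_ci_high=hi,
        pvalue=res.pvalue,
        q=res.extra.get("q", float("nan")),
        q_df=res.extra.get("q_df", float("nan")),
        q_pvalue=res.extra.get("q_pvalue", float("nan")),
        egger_intercept=res.extra.get("egger_intercept", float("nan")),
        egger_intercept_se=res.extra.get("egger_intercept_se", float("nan")),
        egger_intercept_p=res.extra.get("egger_intercept_p", float("nan")),
    )


def _apply_family_fdr(rows: list[ResultRow], alpha: float) -> None:
    """BH-correct main estimates within each disjoint outcome family."""
    for family in sorted({r.family for r in rows}):
        members = [
            r for r in rows
            if r.family == family and r.is_main and r.status == "estimated"
            and np.isfinite(r.pvalue)
        ]
        if not members:
            continue
        adjusted, flags = bh_fdr([r.pvalue for r in members], alpha)
        for r, ap, fl in zip(members, adjusted, flags):
            r.fdr_adjusted_p = float(ap)
            r.fdr_discovery = bool(fl)


def _harmonised_for_instruments(
    exposure: ExposureSpec, instrument_ids: list[str], outcome: OutcomeSpec,
    policy: PalindromePolicy,
) -> HarmonisedSet:
    sub = exposure.table.subset(instrument_ids)
    return harmonise(sub, outcome.table, policy)


def run_drug_target_analysis(plan: AnalysisPlan) -> list[ResultRow]:
    """Drug-target MR across every (gene, stratum, outcome) triple.

    Single-instrument genes use the Wald ratio; multi-instrument genes use
    IVW with multiplicative random effects.  Genes that yielded no
    instrument are reported with status ``uninstrumentable`` — the negative
    screening result is part of the analysis, not an omission.
    """
    rows: list[ResultRow] = []
    for exposure, outcome in plan.pairings():
        iset = exposure.instruments
        genes = sorted(
            {i.gene_id for i in iset.instruments if i.gene_id is not None}
            | set(iset.uninstrumentable)
        )
        for gene_id in genes:
            instruments = iset.for_gene(gene_id)
            if not instruments:
                rows.append(
                    ResultRow(
                        exposure=exposure.label, gene_id=gene_id,
                        stratum=exposure.stratum, outcome=outcome.name,
                        family=outcome.family, method="none", is_main=True,
                        status="uninstrumentable",
                    )
                )
                continue
            ids = [i.variant_id for i in instruments]
            hs = _harmonised_for_instruments(
                exposure, ids, outcome, plan.palindrome_policy
            )
            log.info(
                "drug-target MR %s/%s/%s: %d instruments, %d harmonised",
                gene_id, exposure.stratum, outcome.name, len(ids), hs.n_snps,
            )
            if hs.n_snps == 0:
                rows.append(
                    ResultRow(
                        exposure=exposure.label, gene_id=gene_id,
                        stratum=exposure.stratum, outcome=outcome.name,
                        family=outcome.family, method="none", is_main=True,
                        status="no outcome data",
                    )
                )
                continue
            if hs.n_snps == 1:
                res = wald_ratio(hs.pairs[0])
            else:
                res, het = ivw(hs, random_effects=True)
                res.extra.update(q=het.q, q_df=het.q_df, q_pvalue=het.q_pvalue)
            rows.append(_result_row_from_mr(exposure, gene_id, outcome, res, True))
    _apply_family_fdr(rows, plan.fdr_alpha)
    return rows


def run_conventional_analysis(plan: AnalysisPlan) -> list[ResultRow]:
    """Conventional MR of the exposure on each outcome with sensitivity suite.

    The IVW multiplicative-random-effects estimate is the main analysis;
    MR-Egger, weighted-median and weighted-mode rows are sensitivity
    analyses (uncorrected, flagged ``is_main = False``), with Cochran's Q
    and the Egger intercept as pleiotropy diagnostics.
    """
    rows: list[ResultRow] = []
    seed_counter = 0
    for exposure, outcome in plan.pairings():
        ids = exposure.instruments.variant_ids
        if not ids:
            rows.append(
                ResultRow(
                    exposure=exposure.label, gene_id="",
                    stratum=exposure.stratum, outcome=outcome.name,
                    family=outcome.family, method="none", is_main=True,
                    status="uninstrumentable",
                )
            )
            continue
        hs = _harmonised_for_instruments(
            exposure, ids, outcome, plan.palindrome_policy
        )
        if hs.n_snps == 0:
            rows.append(
                ResultRow(
                    exposure=exposure.label, gene_id="",
                    stratum=exposure.stratum, outcome=outcome.name,
                    family=outcome.family, method="none", is_main=True,
                    status="no outcome data",
                )
            )
            continue
        if plan.seed is None:
            sub_seed = None
        else:
            sub_seed = int(
                np.random.SeedSequence(plan.seed, spawn_key=(seed_counter,))
                .generate_state(1)[0] % (2**31)
            )
        seed_counter += 1
        suite = run_sensitivity_suite(
            hs, n_boot=plan.n_boot, seed=sub_seed, phi=plan.phi
        )
        log.info(
            "conventional MR %s/%s: %d instruments, %d methods",
            exposure.stratum, outcome.name, hs.n_snps, len(suite),
        )
        for res in suite:
            is_main = res.method == "ivw_mre" or (
                res.method == "wald_ratio" and hs.n_snps == 1
            )
            rows.append(_result_row_from_mr(exposure, "", outcome, res, is_main))
    _apply_family_fdr(rows, plan.fdr_alpha)
    return rows


def rows_to_frame(rows: list[ResultRow]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame([vars(r) for r in rows])
    return df[RESULT_COLUMNS]


def write_results(rows: list[ResultRow], path: str | Path) -> None:
    """Write result rows as a tab-separated table with a fixed header."""
    rows_to_frame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> list[ResultRow]:
    """Read back a table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=True)
    out: list[ResultRow] = []
    valid = {f.name for f in dc_fields(ResultRow)}
    for _, rec in df.iterrows():
        kwargs = {}
        for col in RESULT_COLUMNS:
            if col not in valid:
                continue
            val = rec[col]
            if col in ("is_main", "fdr_discovery"):
                val = bool(val)
            elif col == "n_snps":
                val = int(val) if not pd.isna(val) else 0
            elif col in ("exposure", "gene_id", "stratum", "outcome", "family",
                         "method", "status"):
                val = "" if pd.isna(val) else str(val)
            else:
                val = float("nan") if pd.isna(val) else float(val)
            kwargs[col] = val
        out.append(ResultRow(**kwargs))
    return out


def render_forest_text(rows: list[ResultRow]) -> str:
    """Plain-text forest table: one aligned ``OR [CI]`` line per estimate."""
    header = f"{'exposure':<12} {'stratum':<8} {'outcome':<16} {'method':<16} " \
             f"{'n':>4} {'OR [95% CI]':<22} {'p':>9} {'FDR p':>9}"
    lines = [header, "-" * len(header)]
    for r in rows:
        if r.status != "estimated" or not np.isfinite(r.or_decrease):
            est = f"{r.status}"
            p_txt = fdr_txt = ""
        else:
            est = f"{r.or_decrease:.2f} [{r.or_ci_low:.2f}, {r.or_ci_high:.2f}]"
            p_txt = f"{r.pvalue:.2g}"
            fdr_txt = f"{r.fdr_adjusted_p:.2g}" if np.isfinite(r.fdr_adjusted_p) else ""
        label = r.gene_id if r.gene_id else r.exposure
        lines.append(
            f"{label:<12} {r.stratum:<8} {r.outcome:<16} {r.method:<16} "
            f"{r.n_snps:>4} {est:<22} {p_txt:>9} {fdr_txt:>9}"
        )
    return "\n".join(lines) + "\n"
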