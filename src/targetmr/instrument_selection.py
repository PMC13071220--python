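"""Instrument-selection workflows for drug-target and conventional MR.

Drug-target mode screens tissue-specific cis-eQTLs of a candidate target
gene through four filters, in order:

1. *cis window* — within ±1 Mb of the gene's transcription start site;
2. *relevance* — nominal p < 0.05 for the variant's association with the
   glycaemic exposure (HbA1c) and approximated F statistic (beta/se)² > 10
   (strict inequality);
3. *independence* — greedy LD clumping (r² < 0.001 within 10 000 kb),
   ordered by the exposure p-value, performed within gene;
4. *positive-control concordance* — nominal association (p < 0.05) with
   type 2 diabetes in the direction expected if the exposure-raising allele
   raises T2D risk.  T2D is used because it is an established
   metformin-responsive outcome, so a concordant signal supports biological
   relevance of the instrument.

Conventional mode selects genome-wide-significant exposure variants
(p < 5e-8), clumps genome-wide, and drops weak instruments (F <= 10).
Every candidate's fate is retained in a per-filter audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .ld_clump import LDMatrix, clump
from .sumstats import (
    GeneAnnotation,
    PalindromePolicy,
    SummaryStatTable,
    TraitMeta,
    f_statistic,
    harmonise,
)


@dataclass(frozen=True)
class SelectionThresholds:
    """All tunable cut-offs of the selection workflows, with defaults
    matching standard drug-target MR practice."""

    cis_window_bp: int = 1_000_000
    relevance_p: float = 0.05
    f_min: float = 10.0
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    control_p: float = 0.05
    gws_p: float = 5e-8
    #: require direction concordance with the positive control (if False,
    #: literally beta > 0 on the stored orientation is required instead)
    control_concordant: bool = True

    def __post_init__(self) -> None:
        if not (self.cis_window_bp > 0 and self.f_min > 0):
            raise ValidationError("cis_window_bp and f_min must be positive")
        for name in ("relevance_p", "control_p", "gws_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValidationError("clump_r2 must lie in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValidationError("clump_window_kb must be positive")


@dataclass
class Instrument:
    """A variant surviving selection, with its per-filter provenance."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    f_stat: float
    gene_id: Optional[str] = None
    tissue: Optional[str] = None
    filter_trail: dict = field(default_factory=dict)


@dataclass
class InstrumentSet:
    """Selected instruments plus the audit trail of every rejection."""

    exposure_meta: TraitMeta
    instruments: list[Instrument] = field(default_factory=list)
    audit: dict = field(default_factory=dict)  # variant_id -> filter_trail
    uninstrumentable: list[str] = field(default_factory=list)  # gene ids

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    def for_gene(self, gene_id: str) -> list[Instrument]:
        return [i for i in self.instruments if i.gene_id == gene_id]


def cis_filter(
    eqtls: SummaryStatTable, gene: GeneAnnotation, window_bp: int = 1_000_000
) -> SummaryStatTable:
    """Retain variants on the gene's chromosome within ±window of the TSS.

    The window is inclusive at both boundaries.
    """
    df = eqtls.df
    mask = (df["chrom"] == gene.chrom) & (
        (df["pos"] - gene.tss).abs() <= window_bp
    )
    out = SummaryStatTable(meta=eqtls.meta, df=df[mask].reset_index(drop=True))
    return out


def relevance_filter(
    candidates: SummaryStatTable, thresholds: SelectionThresholds
) -> dict[str, dict]:
    """Annotate each candidate's exposure relevance and strength.

    Pass requires ``pvalue < relevance_p`` and F strictly greater than
    ``f_min``; both measured values are recorded in the trail.
    """
    trails: dict[str, dict] = {}
    for _, rec in candidates.df.iterrows():
        f = float(f_statistic(rec["beta"], rec["se"]))
        p_ok = rec["pvalue"] < thresholds.relevance_p
        f_ok = f > thresholds.f_min
        trail = {
            "relevance_p": float(rec["pvalue"]),
            "f_stat": f,
            "relevance": "pass" if (p_ok and f_ok) else "fail",
        }
        if not f_ok:
            trail["relevance_reason"] = "F below threshold"
        elif not p_ok:
            trail["relevance_reason"] = "exposure p above threshold"
        trails[str(rec["variant_id"])] = trail
    return trails


def concordance_filter(
    candidates: SummaryStatTable,
    control: SummaryStatTable,
    thresholds: SelectionThresholds,
    palindrome_policy: PalindromePolicy = PalindromePolicy(),
) -> dict[str, dict]:
    """Screen candidates against the positive-control outcome (T2D).

    The control table is harmonised to the candidates' orientation; pass
    requires control p < ``control_p`` and (by default) the control effect
    sign to agree with the exposure effect sign — i.e. the
    exposure-raising allele must raise control risk.
    """
    trails: dict[str, dict] = {}
    hs = harmonise(candidates, control, palindrome_policy) if len(candidates) else None
    pair_by_id = {p.variant_id: p for p in hs.pairs} if hs else {}
    dropped_by_id = dict(hs.dropped) if hs else {}
    for _, rec in candidates.df.iterrows():
        vid = str(rec["variant_id"])
        pair = pair_by_id.get(vid)
        if pair is None:
            reason = dropped_by_id.get(vid, "no control record")
            trails[vid] = {"concordance": "fail", "concordance_reason": reason}
            continue
        sig = pair.p_outcome < thresholds.control_p
        if thresholds.control_concordant:
            direction_ok = np.sign(pair.beta_outcome) == np.sign(pair.beta_exposure)
        else:
            direction_ok = pair.beta_outcome > 0
        trail = {
            "control_p": pair.p_outcome,
            "control_beta": pair.beta_outcome,
            "concordance": "pass" if (sig and direction_ok) else "fail",
        }
        if not sig:
            trail["concordance_reason"] = "control not significant"
        elif not direction_ok:
            trail["concordance_reason"] = "discordant direction"
        trails[vid] = trail
    return trails


def _merge_trail(audit: dict, vid: str, update: dict) -> None:
    audit.setdefault(vid, {}).update(update)


def select_drug_target_instruments(
    eqtls: dict,
    hba1c: SummaryStatTable,
    t2d: SummaryStatTable,
    genes: list[GeneAnnotation],
    ld: LDMatrix,
    thresholds: SelectionThresholds = SelectionThresholds(),
    palindrome_policy: PalindromePolicy = PalindromePolicy(),
) -> InstrumentSet:
    """Run the full drug-target selection workflow for every gene.

    ``eqtls`` maps ``(gene_id, tissue)`` to that gene's tissue-specific
    cis-eQTL table.  Candidates are pooled across tissues per gene (tissue
    retained as provenance, no cross-tissue meta-analysis), then pushed
    through cis filter -> harmonisation to the exposure -> relevance filter
    -> within-gene clumping -> positive-control concordance.  Genes with no
    surviving instrument are reported in ``uninstrumentable`` — a negative
    screening result, not an error.
    """
    result = InstrumentSet(exposure_meta=hba1c.meta)
    gene_by_id = {g.gene_id: g for g in genes}
    per_gene: dict[str, dict[str, str]] = {g.gene_id: {} for g in genes}
    for (gene_id, tissue), table in eqtls.items():
        if gene_id not in gene_by_id:
            raise ValidationError(f"no annotation for gene {gene_id!r}")
        gene = gene_by_id[gene_id]
        in_cis = set(cis_filter(table, gene, thresholds.cis_window_bp).variant_ids)
        for vid in table.variant_ids:
            key = f"{gene_id}:{vid}"
            if vid in in_cis:
                _merge_trail(result.audit, key, {"cis": "pass", "tissue": tissue})
                # first tissue providing the variant wins as provenance
                per_gene[gene_id].setdefault(vid, tissue)
            else:
                _merge_trail(
                    result.audit, key,
                    {"cis": "fail", "cis_reason": "outside cis window",
                     "tissue": tissue},
                )

    hba1c_idx = hba1c.df.set_index("variant_id")
    for gene_id, candidates in per_gene.items():
        if not candidates:
            result.uninstrumentable.append(gene_id)
            continue
        present = [v for v in candidates if v in hba1c_idx.index]
        for vid in candidates:
            if vid not in hba1c_idx.index:
                _merge_trail(
                    result.audit, f"{gene_id}:{vid}",
                    {"relevance": "fail", "relevance_reason": "no exposure record"},
                )
        cand_table = hba1c.subset(present)
        trails = relevance_filter(cand_table, thresholds)
        for vid, trail in trails.items():
            _merge_trail(result.audit, f"{gene_id}:{vid}", trail)
        passing = [v for v, t in trails.items() if t["relevance"] == "pass"]

        # within-gene clumping ordered by the exposure p-value
        if passing:
            pvals = [(v, float(hba1c_idx.loc[v, "pvalue"])) for v in passing]
            clumped = clump(pvals, ld, thresholds.clump_r2, thresholds.clump_window_kb)
            for vid, index_vid in clumped.removed.items():
                _merge_trail(
                    result.audit, f"{gene_id}:{vid}",
                    {"clump": "fail", "clump_reason": f"clumped to {index_vid}"},
                )
            for vid in clumped.retained:
                _merge_trail(result.audit, f"{gene_id}:{vid}", {"clump": "pass"})
            independent = clumped.retained
        else:
            independent = []

        survivors = []
        if independent:
            conc = concordance_filter(
                hba1c.subset(independent), t2d, thresholds, palindrome_policy
            )
            for vid, trail in conc.items():
                _merge_trail(result.audit, f"{gene_id}:{vid}", trail)
                if trail["concordance"] == "pass":
                    survivors.append(vid)

        if not survivors:
            result.uninstrumentable.append(gene_id)
            continue
        for vid in survivors:
            rec = hba1c_idx.loc[vid]
            result.instruments.append(
                Instrument(
                    variant_id=vid,
                    gene_id=gene_id,
                    tissue=candidates[vid],
                    beta_exposure=float(rec["beta"]),
                    se_exposure=float(rec["se"]),
                    f_stat=float(f_statistic(rec["beta"], rec["se"])),
                    filter_trail=result.audit[f"{gene_id}:{vid}"],
                )
            )
    return result


def select_gws_instruments(
    hba1c: SummaryStatTable,
    ld: LDMatrix,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> InstrumentSet:
    """Conventional-MR instrument selection for the exposure GWAS.

    Retains genome-wide-significant variants (p < ``gws_p``, strict), clumps
    genome-wide (r² < ``clump_r2`` within ``clump_window_kb``), then drops
    weak instruments (F <= ``f_min``).
    """
    result = InstrumentSet(exposure_meta=hba1c.meta)
    df = hba1c.df
    for _, rec in df.iterrows():
        vid = str(rec["variant_id"])
        if rec["pvalue"] < thresholds.gws_p:
            _merge_trail(result.audit, vid, {"gws": "pass", "gws_p": float(rec["pvalue"])})
        else:
            _merge_trail(
                result.audit, vid,
                {"gws": "fail", "gws_reason": "not genome-wide significant",
                 "gws_p": float(rec["pvalue"])},
            )
    gws = df[df["pvalue"] < thresholds.gws_p]
    pvals = list(zip(gws["variant_id"].astype(str), gws["pvalue"].astype(float)))
    clumped = clump(pvals, ld, thresholds.clump_r2, thresholds.clump_window_kb)
    for vid, index_vid in clumped.removed.items():
        _merge_trail(result.audit, vid,
                     {"clump": "fail", "clump_reason": f"clumped to {index_vid}"})
    idx = df.set_index("variant_id")
    for vid in clumped.retained:
        rec = idx.loc[vid]
        f = float(f_statistic(rec["beta"], rec["se"]))
        if f > thresholds.f_min:
            trail = {"clump": "pass", "f_stat": f, "strength": "pass"}
            _merge_trail(result.audit, vid, trail)
            result.instruments.append(
                Instrument(
                    variant_id=vid,
                    beta_exposure=float(rec["beta"]),
                    se_exposure=float(rec["se"]),
                    f_stat=f,
                    filter_trail=result.audit[vid],
                )
            )
        else:
            _merge_trail(
                result.audit, vid,
                {"clump": "pass", "f_stat": f, "strength": "fail",
                 "strength_reason": "F below threshold"},
            )
    return result


def assess_candidate_variant(
    variant_id: str,
    hba1c: SummaryStatTable,
    t2d: SummaryStatTable,
    thresholds: SelectionThresholds = SelectionThresholds(),
    palindrome_policy: PalindromePolicy = PalindromePolicy(),
) -> tuple[Optional[Instrument], dict]:
    """Exploratory single-variant validation (no cis window, no clumping).

    Applies the relevance and positive-control filters to one named variant
    — the screen used for literature-nominated candidates — and returns
    ``(instrument or None, full trail)``.
    """
    if variant_id not in hba1c:
        raise ValidationError(f"variant {variant_id!r} absent from exposure table")
    cand = hba1c.subset([variant_id])
    trail = relevance_filter(cand, thresholds)[variant_id]
    if trail["relevance"] == "pass":
        trail.update(
            concordance_filter(cand, t2d, thresholds, palindrome_policy)[variant_id]
        )
    accepted = trail.get("relevance") == "pass" and trail.get("concordance") == "pass"
    if not accepted:
        return None, trail
    rec = cand.df.iloc[0]
    return (
        Instrument(
            variant_id=variant_id,
            beta_exposure=float(rec["beta"]),
            se_exposure=float(rec["se"]),
            f_stat=float(f_statistic(rec["beta"], rec["se"])),
            filter_trail=trail,
        ),
        trail,
    )
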