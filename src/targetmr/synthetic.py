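"""Synthetic GWAS summary statistics with retained ground truth.

Everything is generated directly on the summary scale — per-variant betas,
SEs and p-values — with no individual-level genotypes, since two-sample MR
consumes only summary data.  Standard errors follow the usual GWAS
approximations: for a continuous trait with standard deviation ``sd``,
``se = sd / sqrt(2 f (1-f) n)``; for a binary trait on the log-odds scale,
``se = 1 / sqrt(2 f (1-f) n v)`` with ``v = case_frac (1 - case_frac)``.
P-values are two-sided normal on ``beta/se``.

The drug-target study generator plants a complete causal chain —
cis-eQTL -> HbA1c -> T2D, with per-gene direct effects on cancer outcomes —
together with a decoy for every selection filter (outside the cis window,
weak instrument strength, discordant positive-control direction, and an
LD duplicate of a true instrument), and records which variants must survive
the whole workflow.  Sample sizes default to the scale of the public GWAS
this kind of analysis draws on (hundreds of thousands for the exposure,
order 10^5 for cancer outcomes, order 10^6 for T2D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ld_clump import LDMatrix
from .sumstats import (
    GeneAnnotation,
    HarmonisedPair,
    HarmonisedSet,
    SUMSTAT_COLUMNS,
    SummaryStatTable,
    TraitMeta,
    build_table,
)

# allele pairs used for generated variants; palindromic pairs excluded so
# harmonisation never has to drop a planted instrument
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

SE_FLOOR = 1e-8


def se_continuous(eaf: np.ndarray, n: float, sd: float = 1.0) -> np.ndarray:
    """GWAS SE approximation for a continuous trait."""
    return np.maximum(sd / np.sqrt(2 * eaf * (1 - eaf) * n), SE_FLOOR)


def se_log_odds(eaf: np.ndarray, n: float, case_frac: float) -> np.ndarray:
    """GWAS SE approximation for a binary trait on the log-odds scale."""
    v = case_frac * (1 - case_frac)
    return np.maximum(1.0 / np.sqrt(2 * eaf * (1 - eaf) * n * v), SE_FLOOR)


def pvalue_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))
    return np.maximum(p, np.finfo(float).tiny)


@dataclass(frozen=True)
class PleiotropyModel:
    """Direct (non-exposure-mediated) variant effects on the outcome.

    ``balanced`` draws effects with mean zero; ``directional`` gives a
    fraction of instruments a mean-``mu`` direct effect.  Effects are drawn
    independently of instrument strength, so the InSIDE assumption holds by
    construction.
    """

    kind: str = "none"  # none | balanced | directional
    mu: float = 0.0
    tau: float = 0.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy kind {self.kind!r}")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if not 0 <= self.fraction <= 1:
            raise ValidationError("fraction must lie in [0, 1]")

    def draw(self, j: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(j)
        alpha = rng.normal(0.0, self.tau, size=j)
        if self.kind == "directional":
            carriers = rng.random(j) < self.fraction
            alpha = np.where(carriers, alpha + self.mu, 0.0)
        return alpha


@dataclass
class TwoSampleTruth:
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    eaf: np.ndarray


@dataclass
class TwoSampleDraw:
    """One simulated exposure/outcome pair, pre-harmonised, plus its truth."""

    pairs: HarmonisedSet
    truth: TwoSampleTruth
    exposure: Optional[SummaryStatTable] = None
    outcome: Optional[SummaryStatTable] = None


def simulate_two_sample(
    theta: float,
    n_snps: int,
    seed: int,
    gamma_range: tuple[float, float] = (0.08, 0.35),
    pleiotropy: PleiotropyModel = PleiotropyModel(),
    n_exposure: float = 344_182,
    n_outcome: float = 100_000,
    case_frac: float = 0.35,
    eaf_range: tuple[float, float] = (0.1, 0.9),
    exposure_sd: float = 1.0,
    tables: bool = False,
) -> TwoSampleDraw:
    """Simulate independent instruments for a two-sample MR experiment.

    Per-allele true exposure effects ``gamma_j`` are uniform on
    ``gamma_range``; observed effects add sampling noise scaled by the
    GWAS SE at the drawn allele frequency and sample size.  Outcome effects
    are ``theta * gamma_j + alpha_j`` (direct effects per the pleiotropy
    model) plus outcome-scale noise.  With ``tables=True`` full
    summary-statistic tables are also returned.
    """
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(*eaf_range, size=n_snps)
    gamma = rng.uniform(*gamma_range, size=n_snps)
    alpha = pleiotropy.draw(n_snps, rng)
    se_x = se_continuous(eaf, n_exposure, exposure_sd)
    se_y = se_log_odds(eaf, n_outcome, case_frac)
    bx = gamma + se_x * rng.standard_normal(n_snps)
    by = theta * gamma + alpha + se_y * rng.standard_normal(n_snps)

    exposure_meta = TraitMeta(
        "exposure", "simulated exposure", "continuous", "unit",
        sample_size=int(n_exposure),
    )
    outcome_meta = TraitMeta(
        "outcome", "simulated outcome", "log_odds", "log-odds",
        sample_size=int(n_outcome), n_cases=int(n_outcome * case_frac),
    )
    px = pvalue_from_z(bx, se_x)
    py = pvalue_from_z(by, se_y)
    pairs = HarmonisedSet(exposure_meta, outcome_meta)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    for j in range(n_snps):
        ea, oa = _ALLELE_PAIRS[allele_idx[j]]
        pairs.pairs.append(
            HarmonisedPair(
                variant_id=f"rs{j + 1:06d}",
                effect_allele=ea,
                beta_exposure=float(bx[j]),
                se_exposure=float(se_x[j]),
                beta_outcome=float(by[j]),
                se_outcome=float(se_y[j]),
                p_exposure=float(px[j]),
                p_outcome=float(py[j]),
            )
        )
    truth = TwoSampleTruth(theta=theta, gamma=gamma, alpha=alpha, eaf=eaf)
    draw = TwoSampleDraw(pairs=pairs, truth=truth)
    if tables:
        ids = [p.variant_id for p in pairs.pairs]
        eas = [p.effect_allele for p in pairs.pairs]
        oas = [_ALLELE_PAIRS[i][1] for i in allele_idx]
        chrom = ["1"] * n_snps
        pos = (np.arange(n_snps) + 1) * 1_000_000
        draw.exposure = _table(
            exposure_meta, ids, chrom, pos, eas, oas, eaf, bx, se_x, px, n_exposure
        )
        draw.outcome = _table(
            outcome_meta, ids, chrom, pos, eas, oas, eaf, by, se_y, py, n_outcome
        )
    return draw


def _table(meta, ids, chrom, pos, ea, oa, eaf, beta, se, p, n) -> SummaryStatTable:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=int),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": np.asarray(eaf, dtype=float),
            "beta": np.asarray(beta, dtype=float),
            "se": np.asarray(se, dtype=float),
            "pvalue": np.asarray(p, dtype=float),
            "n": float(n),
        }
    )[SUMSTAT_COLUMNS]
    return build_table(meta, df)


def simulate_ld_block(
    block_sizes: list[int],
    within_r: float,
    positions: Optional[list[int]] = None,
    seed: int = 0,
    chrom: str = "1",
    variant_ids: Optional[list[str]] = None,
    spacing_bp: int = 5_000,
) -> LDMatrix:
    """Block-diagonal LD: r² = within_r² inside a block, 0 across blocks."""
    if not abs(within_r) < 1:
        raise ValidationError("|within_r| must be < 1")
    k = int(sum(block_sizes))
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:06d}" for i in range(k)]
    if positions is None:
        positions = [(i + 1) * spacing_bp for i in range(k)]
    r2 = np.zeros((k, k))
    start = 0
    for size in block_sizes:
        r2[start:start + size, start:start + size] = within_r**2
        start += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(
        variant_ids=list(variant_ids),
        chroms=[chrom] * k,
        positions=[int(p) for p in positions],
        r2=r2,
    )


# --------------------------------------------------------------------------
# Drug-target study generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeConfig:
    """One simulated cancer outcome GWAS."""

    name: str
    sex: str = "overall"  # sex restriction of the outcome GWAS
    family: str = "primary"
    n: int = 120_000
    case_frac: float = 0.45


@dataclass
class DrugTargetConfig:
    """Study conditions for the planted drug-target scenario.

    Defaults mirror the structure of the real screen: 11 candidate target
    genes of which exactly two are instrumentable, exposure GWAS at UK-
    Biobank scale (overall and sex-specific), a very large binary positive
    control, and one protective gene -> colorectal effect of OR 0.74 per
    unit decrease (log-odds +0.301 per unit increase), every other
    gene-outcome effect null.
    """

    seed: int
    n_genes: int = 11
    n_instrumentable: int = 2
    # per-allele HbA1c effects (mmol/mol) for planted variant classes
    gamma_true: float = 0.18
    gamma_weak: float = 0.01
    gamma_discordant: float = 0.18
    gamma_outside: float = 0.18
    dup_gamma_scale: float = 0.6
    dup_r: float = 0.95
    hba1c_sd: float = 6.5  # mmol/mol, UK-Biobank-scale trait SD
    n_overall: int = 344_182
    n_female: int = 185_022
    n_male: int = 159_160
    sex_effect_sd: float = 0.0  # true sex heterogeneity of gamma (off by default)
    n_t2d: int = 1_812_017
    n_t2d_cases: int = 242_283
    theta_t2d: float = 0.12  # log-odds of T2D per mmol/mol HbA1c
    discordant_alpha: float = -0.06  # direct T2D effect planted on decoys
    n_eqtl: int = 943
    eqtl_beta: float = 0.6  # expression SDs per allele for true cis-eQTLs
    outcomes: tuple = (
        OutcomeConfig("colorectal"),
        OutcomeConfig("lung", n=85_000, case_frac=0.35),
        OutcomeConfig("breast", sex="female", n=228_000, case_frac=0.54),
        OutcomeConfig("prostate", sex="male", n=140_000, case_frac=0.57),
        OutcomeConfig("breast_luminal_like", sex="female", family="secondary",
                      n=120_000, case_frac=0.38),
    )
    # log-odds per mmol/mol increase for (gene index, outcome name);
    # exp(-0.3011) = 0.74 per unit decrease
    theta_cancer: dict = field(
        default_factory=lambda: {(0, "colorectal"): 0.3011050928282265}
    )
    cis_window_bp: int = 1_000_000
    shuffle_orientation: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not 0 < self.n_instrumentable <= self.n_genes:
            raise ValidationError("need 0 < n_instrumentable <= n_genes")


@dataclass
class StudyTruth:
    """Everything needed to score downstream estimates without external data."""

    config: DrugTargetConfig
    gamma: dict  # variant_id -> true per-allele HbA1c effect (overall)
    alpha_t2d: dict  # variant_id -> planted direct T2D effect
    survivors: dict  # gene_id -> variant_id expected to survive selection
    instrumentable: list
    uninstrumentable: list
    theta_cancer: dict  # (gene_id, outcome name) -> log-odds per unit increase
    variant_gene: dict  # variant_id -> gene_id
    variant_class: dict  # variant_id -> planted class label


@dataclass
class SyntheticStudy:
    """A complete simulated study: all trait tables, LD, genes and truth."""

    eqtls: dict  # (gene_id, tissue) -> SummaryStatTable
    hba1c: dict  # stratum -> SummaryStatTable
    t2d: SummaryStatTable
    outcomes: list  # (name, SummaryStatTable, family)
    ld: LDMatrix
    genes: list
    truth: StudyTruth


def _maybe_flip(df: pd.DataFrame, flip_mask: np.ndarray) -> pd.DataFrame:
    """Re-orient selected rows (swap alleles, negate beta, complement eaf)."""
    df = df.copy()
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    df.loc[flip_mask, "effect_allele"] = oa[flip_mask]
    df.loc[flip_mask, "other_allele"] = ea[flip_mask]
    df.loc[flip_mask, "beta"] = -df.loc[flip_mask, "beta"]
    df.loc[flip_mask, "eaf"] = 1.0 - df.loc[flip_mask, "eaf"]
    return df


def simulate_drug_target_study(config: DrugTargetConfig) -> SyntheticStudy:
    """Generate the full planted drug-target study.

    Instrumentable genes carry one strong concordant cis-eQTL plus an LD
    duplicate; every gene also carries decoys exercising each selection
    filter (weak instrument strength, discordant T2D direction, outside the
    cis window, and null background variants).  The truth records exactly
    which variant must survive the workflow for each instrumentable gene.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = [
        GeneAnnotation(
            gene_id=f"G{i + 1:02d}", symbol=f"TGT{i + 1:02d}",
            chrom=str(i + 1), tss=60_000_000,
        )
        for i in range(cfg.n_genes)
    ]
    instrumentable = [g.gene_id for g in genes[: cfg.n_instrumentable]]

    records = []  # variant-level plan
    for i, gene in enumerate(genes):
        tss = gene.tss
        is_instr = gene.gene_id in instrumentable
        if is_instr:
            records += [
                (gene.gene_id, gene.chrom, tss + 200_000, "true", cfg.gamma_true, 0.0),
                (gene.gene_id, gene.chrom, tss + 205_000, "ld_dup",
                 cfg.gamma_true * cfg.dup_gamma_scale, 0.0),
                (gene.gene_id, gene.chrom, tss - 300_000, "weak", cfg.gamma_weak, 0.0),
                (gene.gene_id, gene.chrom, tss - 500_000, "null", 0.0, 0.0),
                (gene.gene_id, gene.chrom, tss + 700_000, "null", 0.0, 0.0),
            ]
        else:
            records += [
                (gene.gene_id, gene.chrom, tss - 300_000, "weak", cfg.gamma_weak, 0.0),
                (gene.gene_id, gene.chrom, tss + 150_000, "weak", cfg.gamma_weak, 0.0),
                (gene.gene_id, gene.chrom, tss + 400_000, "discordant",
                 cfg.gamma_discordant, cfg.discordant_alpha),
                (gene.gene_id, gene.chrom, tss + 1_200_000, "outside",
                 cfg.gamma_outside, 0.0),
                (gene.gene_id, gene.chrom, tss - 650_000, "null", 0.0, 0.0),
                (gene.gene_id, gene.chrom, tss + 820_000, "null", 0.0, 0.0),
            ]

    k = len(records)
    variant_ids = [f"sv{i + 1:04d}" for i in range(k)]
    gene_ids = [r[0] for r in records]
    chroms = [r[1] for r in records]
    positions = np.array([r[2] for r in records], dtype=int)
    classes = [r[3] for r in records]
    gamma = np.array([r[4] for r in records], dtype=float)
    alpha_t2d = np.array([r[5] for r in records], dtype=float)
    eaf = rng.uniform(0.15, 0.85, size=k)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    eas = [_ALLELE_PAIRS[i][0] for i in allele_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in allele_idx]

    # LD: identity plus the planted true/duplicate pairs
    r2 = np.eye(k)
    for i in range(k):
        if classes[i] == "ld_dup":
            # its index variant is the preceding "true" record of the gene
            j = i - 1
            assert classes[j] == "true" and gene_ids[j] == gene_ids[i]
            r2[i, j] = r2[j, i] = cfg.dup_r**2
    ld = LDMatrix(variant_ids=variant_ids, chroms=chroms,
                  positions=[int(p) for p in positions], r2=r2)

    def hba1c_table(stratum: str, n: int) -> SummaryStatTable:
        meta = TraitMeta(
            f"hba1c_{stratum}", "glycated haemoglobin", "continuous",
            "mmol/mol", stratum=stratum, sample_size=n,
        )
        g = gamma.copy()
        if stratum != "overall" and cfg.sex_effect_sd > 0:
            g = g + rng.normal(0.0, cfg.sex_effect_sd, size=k)
        se = se_continuous(eaf, n, cfg.hba1c_sd)
        beta = g + se * rng.standard_normal(k)
        p = pvalue_from_z(beta, se)
        return _table(meta, variant_ids, chroms, positions, eas, oas,
                      eaf, beta, se, p, n)

    hba1c = {
        "overall": hba1c_table("overall", cfg.n_overall),
        "female": hba1c_table("female", cfg.n_female),
        "male": hba1c_table("male", cfg.n_male),
    }

    t2d_meta = TraitMeta(
        "t2d", "type 2 diabetes", "log_odds", "log-odds",
        sample_size=cfg.n_t2d, n_cases=cfg.n_t2d_cases,
    )
    case_frac_t2d = cfg.n_t2d_cases / cfg.n_t2d
    se_t = se_log_odds(eaf, cfg.n_t2d, case_frac_t2d)
    beta_t = cfg.theta_t2d * gamma + alpha_t2d + se_t * rng.standard_normal(k)
    t2d_df = _table(t2d_meta, variant_ids, chroms, positions, eas, oas,
                    eaf, beta_t, se_t, pvalue_from_z(beta_t, se_t), cfg.n_t2d).df
    if cfg.shuffle_orientation:
        t2d_df = _maybe_flip(t2d_df, rng.random(k) < 0.5)
    t2d = build_table(t2d_meta, t2d_df)

    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    theta_cancer_by_id = {
        (genes[gi].gene_id, name): th for (gi, name), th in cfg.theta_cancer.items()
    }
    outcomes = []
    for oc in cfg.outcomes:
        meta = TraitMeta(
            oc.name, f"{oc.name} cancer", "log_odds", "log-odds",
            stratum=oc.sex, sample_size=oc.n, n_cases=int(oc.n * oc.case_frac),
        )
        theta_v = np.array(
            [theta_cancer_by_id.get((gid, oc.name), 0.0) for gid in gene_ids]
        )
        se_o = se_log_odds(eaf, oc.n, oc.case_frac)
        beta_o = theta_v * gamma + se_o * rng.standard_normal(k)
        df = _table(meta, variant_ids, chroms, positions, eas, oas, eaf,
                    beta_o, se_o, pvalue_from_z(beta_o, se_o), oc.n).df
        if cfg.shuffle_orientation:
            df = _maybe_flip(df, rng.random(k) < 0.5)
        outcomes.append((oc.name, build_table(meta, df), oc.family))

    # tissue-specific cis-eQTL tables; the first instrumentable gene is
    # observed in two tissues to exercise cross-tissue pooling
    eqtls = {}
    se_e = se_continuous(eaf, cfg.n_eqtl, 1.0)
    for gene in genes:
        idx = [i for i, gid in enumerate(gene_ids) if gid == gene.gene_id]
        tissues = ["liver"]
        if gene.gene_id == instrumentable[0]:
            tissues.append("muscle")
        for tissue in tissues:
            meta = TraitMeta(
                f"eqtl_{gene.gene_id}_{tissue}",
                f"{gene.symbol} expression ({tissue})", "continuous", "SD",
                sample_size=cfg.n_eqtl,
            )
            has_effect = np.array(
                [classes[i] != "null" for i in idx]
            )
            b_true = np.where(has_effect, cfg.eqtl_beta, 0.0)
            se_sub = se_e[idx]
            beta_e = b_true + se_sub * rng.standard_normal(len(idx))
            eqtls[(gene.gene_id, tissue)] = _table(
                meta,
                [variant_ids[i] for i in idx],
                [chroms[i] for i in idx],
                positions[idx],
                [eas[i] for i in idx],
                [oas[i] for i in idx],
                eaf[idx],
                beta_e,
                se_sub,
                pvalue_from_z(beta_e, se_sub),
                cfg.n_eqtl,
            )

    survivors = {
        gene_ids[i]: variant_ids[i]
        for i in range(k)
        if classes[i] == "true"
    }
    truth = StudyTruth(
        config=cfg,
        gamma=dict(zip(variant_ids, gamma)),
        alpha_t2d=dict(zip(variant_ids, alpha_t2d)),
        survivors=survivors,
        instrumentable=instrumentable,
        uninstrumentable=[g.gene_id for g in genes if g.gene_id not in instrumentable],
        theta_cancer=theta_cancer_by_id,
        variant_gene=dict(zip(variant_ids, gene_ids)),
        variant_class=dict(zip(variant_ids, classes)),
    )
    return SyntheticStudy(
        eqtls=eqtls, hba1c=hba1c, t2d=t2d, outcomes=outcomes,
        ld=ld, genes=genes, truth=truth,
    )


# --------------------------------------------------------------------------
# Conventional (genome-wide) exposure generator
# --------------------------------------------------------------------------

@dataclass
class GwsConfig:
    """Conditions for the genome-wide-significant exposure simulation."""

    seed: int
    k_loci: int = 30
    n_background: int = 150
    n_ld_dups: int = 10
    gamma_range: tuple[float, float] = (0.22, 0.45)  # mmol/mol per allele
    dup_gamma_scale: float = 0.8
    dup_r: float = 0.95
    hba1c_sd: float = 6.5
    n_overall: int = 344_182
    n_female: int = 185_022
    n_male: int = 159_160
    theta_outcome: dict = field(default_factory=dict)  # outcome name -> theta
    outcome_pleiotropy: PleiotropyModel = field(default_factory=PleiotropyModel)
    outcomes: tuple = (
        OutcomeConfig("colorectal"),
        OutcomeConfig("lung", n=85_000, case_frac=0.35),
        OutcomeConfig("breast", sex="female", n=228_000, case_frac=0.54),
        OutcomeConfig("prostate", sex="male", n=140_000, case_frac=0.57),
    )


@dataclass
class GwsStudy:
    hba1c: dict  # stratum -> SummaryStatTable
    outcomes: list  # (name, SummaryStatTable, family)
    ld: LDMatrix
    truth: dict


def simulate_gws_exposure(config: GwsConfig) -> GwsStudy:
    """Plant independent genome-wide-significant exposure loci.

    ``k_loci`` strong loci (genome-wide significant by construction at the
    configured sample size) are spaced far beyond the clumping window, with
    sub-threshold background variants scattered between them and LD
    duplicates attached to the first ``n_ld_dups`` loci.  The truth lists
    the planted loci and their duplicates so selection can be scored.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_loci
    ids, chroms, positions, gamma, classes = [], [], [], [], []
    for i in range(k):
        chrom = str(i % 22 + 1)
        pos = 20_000_000 + 25_000_000 * (i // 22 + 1)
        ids.append(f"gw{i + 1:04d}")
        chroms.append(chrom)
        positions.append(pos)
        gamma.append(rng.uniform(*cfg.gamma_range))
        classes.append("locus")
    for i in range(min(cfg.n_ld_dups, k)):
        ids.append(f"gw{i + 1:04d}_dup")
        chroms.append(chroms[i])
        positions.append(positions[i] + 5_000)
        gamma.append(gamma[i] * cfg.dup_gamma_scale)
        classes.append("ld_dup")
    for i in range(cfg.n_background):
        chrom = str(i % 22 + 1)
        pos = 5_000_000 + 37_000 * i
        ids.append(f"bg{i + 1:04d}")
        chroms.append(chrom)
        positions.append(pos)
        gamma.append(0.0)
        classes.append("background")

    total = len(ids)
    gamma = np.asarray(gamma)
    eaf = rng.uniform(0.15, 0.85, size=total)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total)
    eas = [_ALLELE_PAIRS[i][0] for i in allele_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in allele_idx]

    r2 = np.eye(total)
    for i in range(min(cfg.n_ld_dups, k)):
        j = k + i
        r2[i, j] = r2[j, i] = cfg.dup_r**2
    ld = LDMatrix(variant_ids=ids, chroms=chroms, positions=positions, r2=r2)

    strata = {
        "overall": cfg.n_overall, "female": cfg.n_female, "male": cfg.n_male
    }
    hba1c = {}
    for stratum, n in strata.items():
        meta = TraitMeta(
            f"hba1c_{stratum}", "glycated haemoglobin", "continuous",
            "mmol/mol", stratum=stratum, sample_size=n,
        )
        se = se_continuous(eaf, n, cfg.hba1c_sd)
        beta = gamma + se * rng.standard_normal(total)
        hba1c[stratum] = _table(meta, ids, chroms, positions, eas, oas, eaf,
                                beta, se, pvalue_from_z(beta, se), n)

    outcomes = []
    for oc in cfg.outcomes:
        theta = cfg.theta_outcome.get(oc.name, 0.0)
        meta = TraitMeta(
            oc.name, f"{oc.name} cancer", "log_odds", "log-odds",
            stratum=oc.sex, sample_size=oc.n, n_cases=int(oc.n * oc.case_frac),
        )
        alpha = cfg.outcome_pleiotropy.draw(total, rng)
        se_o = se_log_odds(eaf, oc.n, oc.case_frac)
        beta_o = theta * gamma + alpha + se_o * rng.standard_normal(total)
        outcomes.append(
            (oc.name,
             _table(meta, ids, chroms, positions, eas, oas, eaf, beta_o, se_o,
                    pvalue_from_z(beta_o, se_o), oc.n),
             oc.family)
        )

    truth = {
        "loci": ids[:k],
        "ld_dups": {ids[k + i]: ids[i] for i in range(min(cfg.n_ld_dups, k))},
        "gamma": {vid: float(g) for vid, g in zip(ids, gamma)},
        "theta_outcome": {name: float(v) for name, v in cfg.theta_outcome.items()},
    }
    return GwsStudy(hba1c=hba1c, outcomes=outcomes, ld=ld, truth=truth)
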