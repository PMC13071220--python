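"""Two-sample MR estimators and heterogeneity/pleiotropy diagnostics.

All estimators consume a :class:`~targetmr.sumstats.HarmonisedSet` (or raw
effect arrays) and return an :class:`MRResult` whose ``beta`` is the causal
effect per 1-unit increase of the exposure; for binary outcomes that is a
log odds ratio per exposure unit.  Conversion to an odds ratio per unit
*decrease* is deliberately left to the reporting layer so sign flips happen
in exactly one place.

Implemented methods:

* Wald ratio — single-instrument estimate ``by/bx`` with a first-order
  delta-method SE (second-order available by flag).
* IVW — zero-intercept weighted regression of outcome on exposure effects
  with weights ``1/se_outcome²``; multiplicative random effects inflate the
  SE by ``max(1, sqrt(Q/(J-1)))`` and never deflate it.
* MR-Egger — weighted regression with intercept after orienting all pairs
  to positive exposure effect; the intercept estimates average directional
  pleiotropy under the InSIDE assumption.
* Weighted median — consistent when more than half the weight comes from
  valid instruments; SE by seeded parametric bootstrap.
* Weighted mode — consistent when the largest homogeneous cluster of
  ratio estimates is valid; normal-kernel weighted density over ratios with
  a modified-Silverman bandwidth, maximised on a fixed grid; SE by seeded
  parametric bootstrap.

P-values are two-sided normal throughout, matching the 1.959964 CI
multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .errors import DomainError, EstimationError
from .sumstats import HarmonisedPair, HarmonisedSet

Z_95 = 1.959964
#: exposure effects smaller than this are excluded from multi-SNP sets
#: (per-SNP ratios become numerically unstable)
BX_DEGENERATE = 1e-12


@dataclass
class HeterogeneityStats:
    """Cochran's Q heterogeneity summary for a set of per-SNP ratios."""

    q: float
    q_df: int
    q_pvalue: float
    multiplier: float  # multiplicative random-effects SE inflation (>= 1)


@dataclass
class MRResult:
    """One estimator's causal-effect estimate and diagnostics."""

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    extra: dict = field(default_factory=dict)


def _finish(method: str, n_snps: int, beta: float, se: float, extra=None) -> MRResult:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if se > 0 else 0.0
    if se == 0 and beta == 0:
        p = 1.0
    return MRResult(
        method=method,
        n_snps=n_snps,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pvalue=max(p, np.finfo(float).tiny),
        extra=extra or {},
    )


PairsLike = Union[HarmonisedSet, "list[HarmonisedPair]"]


def _arrays(pairs: PairsLike, drop_degenerate: bool = True):
    if isinstance(pairs, HarmonisedSet):
        bx, sx, by, sy = pairs.arrays()
    else:
        bx = np.array([p.beta_exposure for p in pairs], dtype=float)
        sx = np.array([p.se_exposure for p in pairs], dtype=float)
        by = np.array([p.beta_outcome for p in pairs], dtype=float)
        sy = np.array([p.se_outcome for p in pairs], dtype=float)
    if drop_degenerate:
        keep = np.abs(bx) > BX_DEGENERATE
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    return bx, sx, by, sy


def wald_ratio(pair: HarmonisedPair, second_order_se: bool = False) -> MRResult:
    """Single-instrument causal estimate ``beta_outcome / beta_exposure``.

    The default SE is the first-order delta-method approximation
    ``se_outcome / |beta_exposure|``; ``second_order_se`` adds the term
    propagating exposure uncertainty.
    """
    bx, sx = pair.beta_exposure, pair.se_exposure
    by, sy = pair.beta_outcome, pair.se_outcome
    if bx == 0:
        raise DomainError("Wald ratio undefined for zero exposure effect")
    beta = by / bx
    if second_order_se:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return _finish("wald_ratio", 1, beta, se)


def _ratio_stats(bx, sx, by, sy):
    """Per-SNP Wald ratios and first-order weights 1/se(ratio)^2."""
    theta = by / bx
    se_theta = sy / np.abs(bx)
    w = 1.0 / se_theta**2
    return theta, se_theta, w


def cochran_q(pairs: PairsLike, beta_ref: float) -> HeterogeneityStats:
    """Cochran's Q of per-SNP ratios about ``beta_ref``.

    ``Q = sum_j w_j (theta_j - beta_ref)^2`` with first-order ratio weights;
    df = J - 1 and the p-value is the chi-square upper tail.
    """
    bx, sx, by, sy = _arrays(pairs)
    if len(bx) < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    theta, _, w = _ratio_stats(bx, sx, by, sy)
    q = float(np.sum(w * (theta - beta_ref) ** 2))
    df = len(bx) - 1
    pval = float(stats.chi2.sf(q, df))
    mult = max(1.0, np.sqrt(q / df))
    return HeterogeneityStats(q=q, q_df=df, q_pvalue=max(pval, np.finfo(float).tiny), multiplier=mult)


def ivw(
    pairs: PairsLike, random_effects: bool = True
) -> tuple[MRResult, HeterogeneityStats]:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression).

    ``beta = sum(w bx by) / sum(w bx^2)`` with ``w = 1/se_outcome^2``; the
    fixed-effects SE is ``1/sqrt(sum(w bx^2))``.  With multiplicative random
    effects the SE is inflated by ``max(1, sqrt(Q/(J-1)))`` (inflate-only),
    which absorbs balanced pleiotropy into wider intervals.
    """
    bx, sx, by, sy = _arrays(pairs)
    j = len(bx)
    if j < 2:
        raise EstimationError("IVW needs >= 2 instruments; use wald_ratio for one")
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / denom)
    se_fixed = float(1.0 / np.sqrt(denom))
    het = cochran_q(pairs, beta)
    se = se_fixed * het.multiplier if random_effects else se_fixed
    method = "ivw_mre" if random_effects else "ivw_fe"
    res = _finish(method, j, beta, se)
    return res, het


def mr_egger(pairs: PairsLike) -> MRResult:
    """MR-Egger weighted regression with intercept.

    Pairs are first oriented so every exposure effect is positive (both
    betas flipped where needed — the estimate is invariant to allele
    orientation).  The slope is the causal estimate; the intercept and its
    test, reported in ``extra``, measure average directional pleiotropy
    under InSIDE.  SEs carry the multiplicative random-effects inflation
    ``max(1, residual scale)``.
    """
    bx, sx, by, sy = _arrays(pairs)
    j = len(bx)
    if j < 3:
        raise EstimationError("MR-Egger needs >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) < 1e-14:
        raise EstimationError("degenerate design: all exposure effects equal")
    w = 1.0 / sy**2
    # weighted normal equations for by ~ a + b*bx
    s_w, s_x = np.sum(w), np.sum(w * bx)
    s_xx, s_y, s_xy = np.sum(w * bx**2), np.sum(w * by), np.sum(w * bx * by)
    det = s_w * s_xx - s_x**2
    intercept = (s_xx * s_y - s_x * s_xy) / det
    slope = (s_w * s_xy - s_x * s_y) / det
    resid = by - intercept - slope * bx
    if j > 2:
        sigma2 = float(np.sum(w * resid**2) / (j - 2))
    else:
        sigma2 = 1.0
    infl = max(1.0, sigma2)
    var_slope = infl * s_w / det
    var_int = infl * s_xx / det
    se_slope = float(np.sqrt(var_slope))
    se_int = float(np.sqrt(var_int))
    z_int = intercept / se_int
    extra = {
        "egger_intercept": float(intercept),
        "egger_intercept_se": se_int,
        "egger_intercept_p": float(min(1.0, 2.0 * stats.norm.sf(abs(z_int)))),
        "residual_scale": float(np.sqrt(sigma2)),
    }
    return _finish("egger", j, slope, se_slope, extra)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    frac = cum / np.sum(w)
    if frac[0] >= 0.5:
        return float(theta[0])
    if frac[-1] <= 0.5:
        return float(theta[-1])
    return float(np.interp(0.5, frac, theta))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(bx.shape)
        by_b = by + sy * rng.standard_normal(by.shape)
        bx_b = np.where(np.abs(bx_b) < BX_DEGENERATE, BX_DEGENERATE, bx_b)
        theta, _, w = _ratio_stats(bx_b, sx, by_b, sy)
        ests[b] = point_fn(theta, w)
    return float(np.std(ests, ddof=1))


def weighted_median(
    pairs: PairsLike, n_boot: int = 1000, seed: Optional[int] = None
) -> MRResult:
    """Weighted median of per-SNP ratios (valid with > 50% valid weight).

    The estimate interpolates the cumulative normalised ratio weights at
    0.5; the SE comes from a parametric bootstrap that perturbs both betas
    by their SEs.  ``seed`` is required whenever ``n_boot > 0`` so pipeline
    runs are reproducible.
    """
    bx, sx, by, sy = _arrays(pairs)
    j = len(bx)
    if j < 3:
        raise EstimationError("weighted median needs >= 3 instruments")
    theta, _, w = _ratio_stats(bx, sx, by, sy)
    est = _weighted_median_point(theta, w)
    if n_boot > 0:
        if seed is None:
            raise EstimationError("bootstrap requires an explicit seed")
        se = _bootstrap_se(_weighted_median_point, bx, sx, by, sy, n_boot, seed)
    else:
        se = float("nan")
    if not np.isfinite(se) or se <= 0:
        return MRResult("weighted_median", j, est, float("nan"),
                        float("nan"), float("nan"), float("nan"))
    return _finish("weighted_median", j, est, se)


def _silverman_bandwidth(theta: np.ndarray, phi: float) -> float:
    sd = float(np.std(theta, ddof=1)) if len(theta) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        return 0.0
    spread = min(spread_candidates)
    return phi * 0.9 * spread * len(theta) ** (-0.2)


def _weighted_mode_point(
    theta: np.ndarray, w: np.ndarray, phi: float = 1.0, grid_size: int = 512
) -> float:
    h = _silverman_bandwidth(theta, phi)
    if h == 0.0:
        # all ratios (numerically) identical: the mode is that value
        return float(np.average(theta, weights=w))
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    pairs: PairsLike,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MRResult:
    """Mode-based estimate (valid under plurality-valid instruments).

    Per-SNP ratios are smoothed with a normal kernel of bandwidth
    ``phi * 0.9 * min(sd, IQR/1.34) * J^(-1/5)`` and the weighted density is
    maximised on a 512-point grid spanning the ratios plus three bandwidths.
    SE by seeded parametric bootstrap.
    """
    bx, sx, by, sy = _arrays(pairs)
    j = len(bx)
    if j < 3:
        raise EstimationError("weighted mode needs >= 3 instruments")
    theta, _, w = _ratio_stats(bx, sx, by, sy)
    est = _weighted_mode_point(theta, w, phi)
    if n_boot > 0:
        if seed is None:
            raise EstimationError("bootstrap requires an explicit seed")
        se = _bootstrap_se(
            lambda t, ww: _weighted_mode_point(t, ww, phi), bx, sx, by, sy,
            n_boot, seed,
        )
    else:
        se = float("nan")
    if not np.isfinite(se) or se <= 0:
        return MRResult("weighted_mode", j, est, float("nan"),
                        float("nan"), float("nan"), float("nan"))
    return _finish("weighted_mode", j, est, se)


def run_sensitivity_suite(
    pairs: HarmonisedSet,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    phi: float = 1.0,
) -> list[MRResult]:
    """Run every estimator whose instrument-count precondition holds.

    With one instrument only the Wald ratio applies; with two, per-SNP Wald
    ratios plus IVW; from three instruments the Egger, weighted-median and
    weighted-mode sensitivity analyses join the IVW main analysis, and the
    heterogeneity (Q) and Egger-intercept diagnostics are attached to their
    results' ``extra`` mappings.
    """
    j = pairs.n_snps
    results: list[MRResult] = []
    if j == 0:
        return results
    if j == 1:
        results.append(wald_ratio(pairs.pairs[0]))
        return results
    if j == 2:
        for p in pairs.pairs:
            r = wald_ratio(p)
            r.extra["variant_id"] = p.variant_id
            results.append(r)
    main, het = ivw(pairs, random_effects=True)
    main.extra.update(
        q=het.q, q_df=het.q_df, q_pvalue=het.q_pvalue, q_multiplier=het.multiplier
    )
    results.append(main)
    if j >= 3:
        results.append(mr_egger(pairs))
        results.append(weighted_median(pairs, n_boot=n_boot, seed=seed))
        results.append(weighted_mode(pairs, phi=phi, n_boot=n_boot, seed=seed))
    return results
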