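# Methods

## Model and assumptions

Two-sample MR treats genetic variants as instruments for an exposure. A
variant j with per-allele exposure effect β<sub>Xj</sub> (SE
SE<sub>Xj</sub>) and outcome effect β<sub>Yj</sub> (SE SE<sub>Yj</sub>,
log-odds scale for binary outcomes) identifies the causal effect θ under
the instrumental-variable assumptions: relevance (the variant affects the
exposure), independence (no confounding of variant and outcome) and
exclusion restriction (no effect on the outcome except through the
exposure). In drug-target mode the "exposure" is target modulation proxied
through HbA1c, so instruments are restricted to cis variants of the target
gene and relevance is measured on the HbA1c association.

### Estimators

All estimators consume harmonised (β<sub>Xj</sub>, β<sub>Yj</sub>) pairs on
a common effect allele and return θ per 1-unit exposure *increase*; the
reporting layer alone converts to OR per unit decrease, so the sign flip
has exactly one site.

- **Wald ratio** (J = 1): θ̂ = β<sub>Y</sub>/β<sub>X</sub>, SE
  SE<sub>Y</sub>/|β<sub>X</sub>| (first-order delta method; a second-order
  option adds the β<sub>X</sub> uncertainty term
  √(SE<sub>Y</sub>²/β<sub>X</sub>² + β<sub>Y</sub>²SE<sub>X</sub>²/β<sub>X</sub>⁴)).
- **IVW** (J ≥ 2): zero-intercept weighted regression of β<sub>Y</sub> on
  β<sub>X</sub> with weights 1/SE<sub>Y</sub>²; fixed-effects SE
  1/√(Σ w<sub>j</sub> β<sub>Xj</sub>²). Multiplicative random effects
  multiply the SE by max(1, √(Q/(J−1))) — inflate-only, the standard
  behaviour, so heterogeneity can widen but never narrow intervals.
- **Cochran's Q**: Q = Σ w<sub>j</sub>(θ̂<sub>j</sub> − θ̂)² over per-SNP
  ratios with first-order ratio weights w<sub>j</sub> =
  β<sub>Xj</sub>²/SE<sub>Yj</sub>²; df = J−1, chi-square upper-tail p.
  This weighting makes the IVW estimate algebraically identical to the
  inverse-variance-weighted mean of the ratios (asserted to 1e-10 in
  tests).
- **MR-Egger** (J ≥ 3): pairs are first oriented to β<sub>X</sub> > 0
  (flipping both betas — estimates are invariant to allele orientation),
  then weighted regression *with* intercept; the slope estimates θ under
  InSIDE, and the intercept estimates mean directional pleiotropy. SEs use
  multiplicative inflation max(1, residual scale).
- **Weighted median** (J ≥ 3): ratios sorted, cumulative normalised weights
  (cum − w/2)/W interpolated linearly at 0.5. Consistent while > 50% of
  ratio weight comes from valid instruments.
- **Weighted mode** (J ≥ 3): weighted normal-kernel density over ratios,
  bandwidth h = φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (modified Silverman rule,
  φ defaults to 1), maximised over a 512-point grid spanning the ratios ±3h.
  If every spread measure is zero (all ratios identical) the common value
  is returned. Grid maximisation is exactly reproducible; its resolution
  (range/511) bounds the scale-equivariance error checked in tests.
- **Bootstrap SEs** (median, mode): parametric — both betas perturbed by
  their SEs, n_boot = 1000 draws by default, explicit integer seed required
  whenever a bootstrap runs, so pipeline outputs are byte-reproducible.

P-values are two-sided normal throughout, consistent with the 1.959964 CI
multiplier; a t-option was considered and rejected to keep CI and p
mutually consistent. Exposure effects with |β<sub>X</sub>| < 1e-12 are
excluded from multi-SNP sets (ratio instability) with an audit entry.

### Selection thresholds (defaults)

| parameter | default | meaning |
|---|---|---|
| cis_window_bp | 1 000 000 | ±1 Mb of the TSS defines cis |
| relevance_p | 0.05 | nominal exposure association |
| f_min | 10 | strict F > 10 weak-instrument screen |
| clump_r2 / clump_window_kb | 0.001 / 10 000 | independence filter |
| control_p | 0.05 | positive-control (T2D) nominal significance |
| gws_p | 5e-8 | genome-wide significance, conventional mode |

Boundary semantics: the cis window is inclusive at ±1 Mb; relevance and
control use strict `p < threshold`; instrument strength uses strict
`F > f_min` (F exactly at the threshold fails); clumping removes at
`r² ≥ clump_r2` within the inclusive window, ordered by ascending exposure
p with ties broken by position then variant ID for determinism.

## Design choices where the field's practice varies

- **Palindromic variants** (A/T, C/G): dropped when either side's EAF is
  missing or min(EAF, 1−EAF) > 0.42 on either side; otherwise aligned by
  frequency concordance (both sides of 0.5). A `drop_all` policy is
  available. Strand mismatches for non-palindromic variants are resolved by
  complementing, with a flag recorded.
- **Positive control direction**: "positive association with T2D" is
  implemented as direction concordance — the HbA1c-raising allele must
  raise T2D risk at p < 0.05 — since a fixed-orientation `beta > 0` reading
  is orientation-dependent; a `control_concordant=False` switch gives the
  literal reading.
- **Clumping scope**: within gene in drug-target mode (one independence
  decision per target), genome-wide in conventional mode.
- **Tissue pooling**: candidates are pooled across tissues per gene with
  tissue kept as provenance; no cross-tissue meta-analysis is attempted.
- **FDR scope**: BH at α = 0.05 within each outcome family (primary,
  secondary), pooling genes and exposure strata, over main estimates only;
  sensitivity rows are reported uncorrected and flagged `is_main = False`.
- **Sex pairing**: sex-specific outcomes are analysed with the matching
  sex-specific exposure only; non-sex-specific outcomes against overall
  and both sex-specific exposures.
- **Uninstrumentable targets** stay in the output with a status — a screen
  in which most candidate genes yield no valid instrument is a result, not
  a failure mode.

## The synthetic generator

Summary statistics are generated directly on the summary scale (no
individual-level genotypes): for a continuous trait,
SE = sd/√(2f(1−f)n); for a binary trait on log-odds,
SE = 1/√(2f(1−f)·n·v), v = case_frac·(1−case_frac); observed beta = true
beta + SE·noise; p = two-sided normal. Generated SEs therefore scale
exactly as 1/√n and p-values are exactly consistent with beta/SE, both
asserted in tests.

`simulate_two_sample` plants γ<sub>j</sub> ~ U(0.08, 0.35) per-allele
exposure effects (sd = 1 scale), β<sub>Yj</sub> = θγ<sub>j</sub> +
α<sub>j</sub> + noise, with pleiotropy α<sub>j</sub> drawn independently of
γ<sub>j</sub> (InSIDE holds by construction): none, balanced
(mean-zero, sd τ) or directional (mean μ on a fraction of instruments).
Exposure n = 344 182 at these effect sizes gives F in the thousands, so
weak-instrument bias is negligible in estimator-calibration experiments —
those experiments test the estimators, not the strength screen.

`simulate_drug_target_study` (defaults = the study conditions): 11
candidate genes on separate chromosomes, two instrumentable. HbA1c uses a
trait sd of 6.5 mmol/mol and UK-Biobank-scale strata (n = 344 182 /
185 022 / 159 160); the positive control is a binary GWAS of n = 1 812 017
with 242 283 cases and θ<sub>T2D</sub> = 0.12 log-odds per mmol/mol; cancer
outcomes are binary GWAS of order 10⁵. True instruments carry γ = 0.18
mmol/mol per allele (F ≈ 110–140 at the overall n, the scale of a strong
glycaemic variant); decoys exercise every filter: outside-window (±1.2 Mb),
weak (γ = 0.01, expected F ≈ 1), T2D-discordant (strong HbA1c effect with a
planted direct T2D effect of −0.06 flipping the control direction), an LD
duplicate of each true instrument (r = 0.95, γ scaled by 0.6 so the true
variant wins the p-ordering almost surely), and null background variants.
One planted gene→colorectal effect of +0.3011 log-odds per mmol/mol
increase (OR 0.74 per unit decrease); all other gene-outcome effects are
null. Sex-specific effects equal the overall effect by default (no true
sex heterogeneity; a knob exists). Allele orientations of control/outcome
tables are randomly flipped so harmonisation is always exercised.

`simulate_gws_exposure` plants 30 independent genome-wide-significant loci
(γ ~ U(0.22, 0.45), minimum planted z ≈ 10, so all stay below 5e-8 with
overwhelming probability), 150 sub-threshold background variants and 10 LD
duplicates.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic LD maps (block-diagonal r² only),
correlated sampling noise between variants in LD, sample overlap between
exposure and outcome GWAS, population stratification, winner's curse in
instrument selection, and genuine sex heterogeneity. Colocalization of
eQTL and biomarker signals is out of scope entirely; recovery of a planted
effect says nothing about LD-confounding of a real single-variant result.

## Validation experiments (sizes and tolerances)

Run by `tests/test_acceptance.py` and recomputed by
`scripts/acceptance.py`; sizes chosen to make Monte-Carlo error small
relative to the checked tolerances while keeping a full run around a
minute on one CPU.

- Oracle equivalence: IVW and Egger agree with statsmodels WLS (through the
  origin / with intercept) to 1e-10 on 100 random instances (J ≤ 50);
  clumping agrees exactly with a brute-force greedy re-implementation on
  100 random instances (≤ 200 variants, 3 chromosomes).
- Recovery: θ ∈ {−0.3, 0, 0.2}, J = 50, 500 replicates, no pleiotropy —
  each estimator's mean within 3 MC SEs of θ.
- Calibration: IVW-MRE coverage under balanced pleiotropy (τ = 0.01,
  1000 replicates) required in [0.93, 0.97] — multiplicative inflation with
  z quantiles is known to run slightly below nominal; Q rejection under
  homogeneity (2000 replicates, J = 10) in [0.03, 0.07].
- Robustness: 40% of instruments with directional pleiotropy (μ = 0.02,
  τ = 0.005): |bias(weighted median)| < |bias(IVW)|, and the Egger
  intercept minus the realised mean pleiotropy (a paired comparison that
  removes the draw-to-draw variation in planted α) within 3 MC SEs of 0
  over 500 replicates.
- Workflow: 200 replicate default studies — the overall-stratum selection
  returns exactly the planted survivor set (and uninstrumentable set) in
  ≥ 95% of replicates (measured ≈ 0.95–0.98; residual failures are the
  rare noise flips of the LD-duplicate p-ordering or a weak decoy crossing
  F > 10), the planted effect is an FDR discovery in ≥ 90% (measured
  ≈ 1.0), planted nulls are flagged in ≤ 10% (measured ≈ 2%), and the mean
  recovered OR per unit decrease is within 0.05 of the planted 0.74.
- Determinism: identical config and seeds produce byte-identical study
  directories and result tables end-to-end.

## Known limitations

Single-variant drug-target results inherit all caveats of one-instrument
MR (no heterogeneity diagnostics possible, LD confounding unaddressed
without colocalization). The binary-trait SE approximation ignores
covariate adjustment and case-control imbalance corrections used by real
GWAS. The weighted-mode bandwidth rule is one of several in circulation;
φ is exposed for sensitivity. MR-PRESSO, contamination-mixture,
multivariable MR and Steiger filtering are deliberately out of scope.
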