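# targetmr

Two-sample Mendelian randomization (MR) for drug-target screens on GWAS
summary statistics — with a synthetic study generator carrying known ground
truth, so the entire pipeline can be run and validated without downloading
any real GWAS data.

## The scientific problem

Drug-target MR asks whether pharmacologically modulating a specific protein
is likely to affect a disease, using genetics as the experiment nature
already ran. For a glucose-lowering drug such as metformin, the recipe is:

1. **Instrument selection.** For each candidate target gene, take
   tissue-specific *cis*-eQTLs (variants within ±1 Mb of the transcription
   start site that regulate the gene's expression) and keep those that are
   (i) *relevant* — nominally associated (p < 0.05) with the glycaemic
   biomarker HbA1c with approximated F statistic
   (β<sub>HbA1c</sub>/SE<sub>HbA1c</sub>)² strictly greater than 10;
   (ii) *independent* — LD-clumped at r² < 0.001 within a 10 000 kb window;
   and (iii) *biologically validated* — nominally associated (p < 0.05)
   with type 2 diabetes, a known drug-responsive outcome, in the direction
   expected if the HbA1c-raising allele raises T2D risk.
2. **Estimation.** With one instrument per gene, the Wald ratio
   β<sub>outcome</sub>/β<sub>exposure</sub>; with several, inverse-variance
   weighted (IVW) regression with multiplicative random effects. Effects
   are reported as odds ratios per 1 mmol/mol *decrease* in HbA1c, the
   direction a drug moves the biomarker: OR = exp(−β).
3. **Sensitivity.** For the complementary conventional MR of HbA1c itself
   (genome-wide significant instruments, p < 5×10⁻⁸), MR-Egger, weighted
   median and weighted mode, plus Cochran's Q and the MR-Egger intercept as
   heterogeneity/pleiotropy diagnostics.
4. **Multiplicity.** Benjamini–Hochberg FDR at α = 0.05, applied separately
   to the primary- and secondary-outcome families.

The package implements every step as a library (`targetmr.*`) with a thin
`targetmr` CLI, and a generator (`targetmr.synthetic`) that plants a full
causal chain — cis-eQTL → HbA1c → T2D, with per-gene effects on cancer
outcomes — together with decoys for every selection filter, so tests can
check that the workflow recovers exactly the planted truth.

## Worked example

Simulate the default planted study (11 candidate target genes, of which
exactly two are instrumentable; one planted protective gene→colorectal
effect of OR 0.74 per mmol/mol decrease), run the analysis, and render the
text forest table:

```
$ targetmr simulate --seed 5 --out-dir study
$ targetmr mr --study-dir study --out results.tsv --seed 3
$ targetmr report --results results.tsv
```

Output (overall-stratum rows):

```
exposure     stratum  outcome          method              n OR [95% CI]                    p     FDR p
-------------------------------------------------------------------------------------------------------
G01          overall  colorectal       wald_ratio          1 0.74 [0.67, 0.82]        7.5e-09     4e-08
G02          overall  colorectal       wald_ratio          1 0.94 [0.86, 1.04]           0.21      0.57
G03          overall  colorectal       none                0 uninstrumentable
...
G01          overall  lung             wald_ratio          1 0.95 [0.84, 1.08]           0.46      0.68
G02          overall  lung             wald_ratio          1 0.98 [0.87, 1.10]           0.71      0.73
```

Reading this: gene `G01` carries the planted protective effect — its single
surviving instrument gives a Wald-ratio OR of 0.74 per mmol/mol HbA1c
decrease (95% CI 0.67–0.82), an FDR discovery; `G02` is instrumentable but
its planted effect is null (OR 0.94, CI spans 1); the other nine genes had
no variant surviving the relevance/strength/independence/T2D-concordance
filters and are reported as uninstrumentable rather than dropped. The
`--mode conventional` variant of `simulate` exercises the genome-wide
pipeline (IVW main analysis plus Egger/median/mode sensitivity rows).

Intermediate artifacts are available too: `targetmr select-instruments
--study-dir study --out-dir sel` writes per-stratum instrument tables and a
per-candidate audit of every filter decision.

## Layout

- `targetmr.sumstats` — summary-statistics data model, TSV dialect I/O,
  allele harmonisation (strand complements, palindrome policy), F statistic
- `targetmr.ld_clump` — LD-matrix handling and greedy p-ordered clumping
- `targetmr.instrument_selection` — drug-target and genome-wide selection
  workflows with per-candidate audit trails
- `targetmr.mr_estimators` — Wald ratio, IVW(-MRE), MR-Egger, weighted
  median, weighted mode, Cochran's Q, sensitivity suite
- `targetmr.reporting` — analysis plans, OR-per-decrease conversion,
  family-wise BH FDR, result tables, text forest rendering
- `targetmr.synthetic` — ground-truth study generators;
  `targetmr.experiments` — seeded validation experiments
- `targetmr.studydir` / `targetmr.cli` — directory round-trip and CLI

See `docs/methods.md` for the statistical model, generator assumptions and
numerical choices.
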