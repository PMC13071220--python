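"""Drug-target and genome-wide instrument-selection workflows."""

import numpy as np
import pytest

from targetmr.errors import ValidationError
from targetmr.instrument_selection import (
    SelectionThresholds,
    assess_candidate_variant,
    cis_filter,
    concordance_filter,
    relevance_filter,
    select_drug_target_instruments,
    select_gws_instruments,
)
from targetmr.ld_clump import LDMatrix
from targetmr.sumstats import GeneAnnotation, f_statistic
from targetmr.synthetic import DrugTargetConfig, GwsConfig, simulate_drug_target_study, simulate_gws_exposure

from conftest import BINARY_META, make_table

GENE = GeneAnnotation("G1", "TGT1", "1", 50_000_000)


def identity_ld(table):
    ids = table.variant_ids
    return LDMatrix(
        variant_ids=ids,
        chroms=[str(c) for c in table.df["chrom"]],
        positions=[int(p) for p in table.df["pos"]],
        r2=np.eye(len(ids)),
    )


class TestCisFilter:
    def test_boundary_inclusive(self):
        table = make_table([{"pos": GENE.tss + 1_000_000}])
        assert len(cis_filter(table, GENE, 1_000_000)) == 1

    def test_boundary_exclusive_beyond(self):
        table = make_table([{"pos": GENE.tss + 1_000_001}])
        assert len(cis_filter(table, GENE, 1_000_000)) == 0

    def test_other_chromosome_removed(self):
        table = make_table([{"pos": GENE.tss, "chrom": "2"}])
        assert len(cis_filter(table, GENE, 1_000_000)) == 0

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(11)
        rows = [
            {"variant_id": f"rs{i}", "pos": int(rng.integers(1, 120_000_000)),
             "chrom": str(rng.integers(1, 3))}
            for i in range(200)
        ]
        table = make_table(rows)
        got = set(cis_filter(table, GENE, 1_000_000).variant_ids)
        expected = {
            r["variant_id"] for r in rows
            if r["chrom"] == GENE.chrom and abs(r["pos"] - GENE.tss) <= 1_000_000
        }
        assert got == expected


class TestRelevanceFilter:
    def make_candidate(self, p, f):
        # choose beta/se giving the requested F; p is set directly
        se = 0.01
        return make_table([{"beta": np.sqrt(f) * se, "se": se, "pvalue": p}])

    def test_both_criteria_met_passes(self):
        trails = relevance_filter(self.make_candidate(0.04, 11), SelectionThresholds())
        assert trails["rs1"]["relevance"] == "pass"

    def test_weak_f_fails_with_reason(self):
        trails = relevance_filter(self.make_candidate(0.04, 9.9), SelectionThresholds())
        assert trails["rs1"]["relevance"] == "fail"
        assert trails["rs1"]["relevance_reason"] == "F below threshold"

    def test_f_exactly_at_threshold_fails_strictly(self):
        # beta/se = 3 exactly in binary floating point, so F == 9.0 exactly
        table = make_table([{"beta": 0.75, "se": 0.25, "pvalue": 1e-3}])
        assert f_statistic(0.75, 0.25) == 9.0
        thresholds = SelectionThresholds(f_min=9.0)
        trails = relevance_filter(table, thresholds)
        assert trails["rs1"]["relevance"] == "fail"
        assert trails["rs1"]["relevance_reason"] == "F below threshold"
        just_above = make_table([{"beta": 0.7500001, "se": 0.25, "pvalue": 1e-3}])
        assert relevance_filter(just_above, thresholds)["rs1"]["relevance"] == "pass"


class TestConcordanceFilter:
    def control(self, beta, p, **kw):
        return make_table([{"beta": beta, "pvalue": p, **kw}], meta=BINARY_META)

    def candidates(self, beta=0.03):
        return make_table([{"beta": beta, "pvalue": 1e-5}])

    def test_concordant_significant_passes(self):
        trails = concordance_filter(
            self.candidates(0.03), self.control(0.08, 0.001), SelectionThresholds()
        )
        assert trails["rs1"]["concordance"] == "pass"

    def test_discordant_direction_fails(self):
        trails = concordance_filter(
            self.candidates(0.03), self.control(-0.08, 0.001), SelectionThresholds()
        )
        assert trails["rs1"]["concordance_reason"] == "discordant direction"

    def test_not_significant_fails(self):
        trails = concordance_filter(
            self.candidates(0.03), self.control(0.08, 0.06), SelectionThresholds()
        )
        assert trails["rs1"]["concordance_reason"] == "control not significant"

    def test_missing_control_record_fails(self):
        control = make_table([{"variant_id": "other"}], meta=BINARY_META)
        with pytest.warns(UserWarning):
            trails = concordance_filter(
                self.candidates(), control, SelectionThresholds()
            )
        assert trails["rs1"]["concordance_reason"] == "no control record"

    def test_literal_positive_switch(self):
        # with concordance off, a negative exposure effect with negative
        # control effect fails the literal beta>0 reading
        thresholds = SelectionThresholds(control_concordant=False)
        trails = concordance_filter(
            self.candidates(-0.03), self.control(-0.08, 0.001), thresholds
        )
        assert trails["rs1"]["concordance"] == "fail"


class TestDrugTargetWorkflow:
    def test_planted_study_recovers_truth(self, drug_study):
        study = drug_study
        iset = select_drug_target_instruments(
            study.eqtls, study.hba1c["overall"], study.t2d, study.genes, study.ld
        )
        got = {i.gene_id: i.variant_id for i in iset.instruments}
        assert got == study.truth.survivors
        assert set(iset.uninstrumentable) == set(study.truth.uninstrumentable)

    def test_weak_gene_trail_reports_f(self, drug_study):
        study = drug_study
        iset = select_drug_target_instruments(
            study.eqtls, study.hba1c["overall"], study.t2d, study.genes, study.ld
        )
        weak_ids = [
            f"{study.truth.variant_gene[v]}:{v}"
            for v, cls in study.truth.variant_class.items()
            if cls == "weak"
        ]
        reasons = {result for k in weak_ids
                   for result in [iset.audit[k].get("relevance_reason", "")]}
        assert "F below threshold" in reasons

    def test_ld_duplicate_clumped_to_true_instrument(self, drug_study):
        study = drug_study
        iset = select_drug_target_instruments(
            study.eqtls, study.hba1c["overall"], study.t2d, study.genes, study.ld
        )
        dups = [v for v, c in study.truth.variant_class.items() if c == "ld_dup"]
        for dup in dups:
            gene = study.truth.variant_gene[dup]
            trail = iset.audit[f"{gene}:{dup}"]
            assert trail["clump"] == "fail"
            assert study.truth.survivors[gene] in trail["clump_reason"]

    def test_audit_covers_every_candidate(self, drug_study):
        study = drug_study
        iset = select_drug_target_instruments(
            study.eqtls, study.hba1c["overall"], study.t2d, study.genes, study.ld
        )
        expected_keys = set()
        for (gene_id, _tissue), table in study.eqtls.items():
            expected_keys |= {f"{gene_id}:{v}" for v in table.variant_ids}
        assert set(iset.audit) == expected_keys
        for inst in iset.instruments:
            trail = iset.audit[f"{inst.gene_id}:{inst.variant_id}"]
            assert trail["relevance"] == "pass"
            assert trail["concordance"] == "pass"

    def test_zero_effect_eqtls_make_all_genes_uninstrumentable(self):
        cfg = DrugTargetConfig(
            seed=3, gamma_true=0.0, gamma_weak=0.0,
            gamma_discordant=0.0, gamma_outside=0.0,
        )
        study = simulate_drug_target_study(cfg)
        iset = select_drug_target_instruments(
            study.eqtls, study.hba1c["overall"], study.t2d, study.genes, study.ld
        )
        assert iset.instruments == []
        assert len(iset.uninstrumentable) == cfg.n_genes

    def test_loosening_thresholds_never_shrinks_set(self, drug_study):
        study = drug_study
        args = (study.eqtls, study.hba1c["overall"], study.t2d,
                study.genes, study.ld)
        strict = select_drug_target_instruments(*args, SelectionThresholds())
        loose = select_drug_target_instruments(
            *args,
            SelectionThresholds(relevance_p=0.5, f_min=1.0, clump_r2=0.5,
                                control_p=0.5),
        )
        assert set(strict.variant_ids) <= set(loose.variant_ids)


class TestGwsSelection:
    def test_planted_loci_count_recovered(self):
        study = simulate_gws_exposure(GwsConfig(seed=4, k_loci=12, n_background=60,
                                                n_ld_dups=4))
        iset = select_gws_instruments(study.hba1c["overall"], study.ld)
        assert len(iset.instruments) == 12
        assert all(i.f_stat > 10 for i in iset.instruments)

    def test_background_only_yields_zero(self):
        study = simulate_gws_exposure(GwsConfig(seed=4, k_loci=0, n_background=80,
                                                n_ld_dups=0))
        iset = select_gws_instruments(study.hba1c["overall"], study.ld)
        assert iset.instruments == []

    def test_gws_boundary_p_excluded(self):
        table = make_table([
            {"variant_id": "at", "pvalue": 6e-8, "beta": 0.3, "se": 0.02},
            {"variant_id": "below", "pvalue": 4e-8, "beta": 0.3, "se": 0.02},
        ])
        iset = select_gws_instruments(table, identity_ld(table))
        assert iset.variant_ids == ["below"]

    def test_degenerate_thresholds_keep_all_strong(self):
        table = make_table([
            {"variant_id": f"v{i}", "pvalue": 0.5, "beta": 0.5, "se": 0.02}
            for i in range(5)
        ])
        thresholds = SelectionThresholds(gws_p=1.0, clump_r2=1.0)
        iset = select_gws_instruments(table, identity_ld(table), thresholds)
        assert len(iset.instruments) == 5


class TestAssessCandidate:
    def strong_tables(self):
        # F = (0.35/0.0314)^2 ~ 124: the scale of a strong glycaemic variant
        hba1c = make_table([{"variant_id": "rsX", "beta": 0.35, "se": 0.0314,
                             "pvalue": 1e-28}])
        t2d = make_table([{"variant_id": "rsX", "beta": 0.05, "se": 0.004,
                           "pvalue": 1e-20}], meta=BINARY_META)
        return hba1c, t2d

    def test_strong_variant_accepted(self):
        hba1c, t2d = self.strong_tables()
        inst, trail = assess_candidate_variant("rsX", hba1c, t2d)
        assert inst is not None
        assert inst.f_stat == pytest.approx(124, rel=0.01)
        assert trail["concordance"] == "pass"

    def test_weak_variant_rejected_for_strength(self):
        hba1c = make_table([{"variant_id": "rsW", "beta": 0.003, "se": 0.0031,
                             "pvalue": 0.33}])
        _, t2d = self.strong_tables()
        inst, trail = assess_candidate_variant("rsW", hba1c, t2d)
        assert inst is None
        assert trail["relevance_reason"] == "F below threshold"
        assert trail["f_stat"] < 1

    def test_variant_missing_from_control_rejected(self):
        hba1c, _ = self.strong_tables()
        t2d = make_table([{"variant_id": "other"}], meta=BINARY_META)
        with pytest.warns(UserWarning):
            inst, trail = assess_candidate_variant("rsX", hba1c, t2d)
        assert inst is None
        assert trail["concordance_reason"] == "no control record"

    def test_variant_absent_from_exposure_is_error(self):
        hba1c, t2d = self.strong_tables()
        with pytest.raises(ValidationError, match="ghost"):
            assess_candidate_variant("ghost", hba1c, t2d)
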