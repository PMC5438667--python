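import pytest

import snpmeta as sm
from snpmeta import GeneticModel


class TestSubgroups:
    @pytest.mark.parametrize(
        "model,factor,level,k,or_,lo,hi",
        [
            (GeneticModel.ALLELE, "ethnicity", "Caucasian", 9, 1.29, 1.21, 1.37),
            (GeneticModel.ALLELE, "ethnicity", "Asian", 2, 1.04, 0.55, 1.99),
            (GeneticModel.RECESSIVE, "soc", "HB", 5, 1.36, 1.03, 1.80),
            (GeneticModel.DOMINANT, "soc", "PB", 8, 1.28, 1.22, 1.34),
            (GeneticModel.DOMINANT, "ethnicity", "Caucasian", 9, 1.34, 1.24, 1.46),
        ],
    )
    def test_stratum_pools_match_published_values(
        self, fixture_set, model, factor, level, k, or_, lo, hi
    ):
        results = {sg.level: sg for sg in sm.subgroup_analysis(fixture_set, model, factor)}
        sg = results[level]
        assert sg.k == k
        assert sg.result.pooled_or == pytest.approx(or_, abs=0.01)
        assert sg.result.ci_low == pytest.approx(lo, abs=0.01)
        assert sg.result.ci_high == pytest.approx(hi, abs=0.01)

    def test_asian_allele_stratum_is_null(self, fixture_set):
        results = {sg.level: sg for sg in sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "ethnicity")}
        assert results["Asian"].result.p_value == pytest.approx(0.899, abs=0.005)

    @pytest.mark.parametrize("factor", ["ethnicity", "soc"])
    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_strata_partition_the_study_set(self, fixture_set, model, factor):
        results = sm.subgroup_analysis(fixture_set, model, factor)
        pooled_ids = [sid for sg in results for sid in sg.study_ids]
        assert sorted(pooled_ids) == sorted(fixture_set.ids)
        assert sum(sg.k for sg in results) == len(fixture_set)

    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_single_study_stratum_equals_crude_estimate(self, fixture_set, model):
        results = {sg.level: sg for sg in sm.subgroup_analysis(fixture_set, model, "ethnicity")}
        for level, sid in [("African-American", "Chang2011"), ("Mixed", "Haiman2013")]:
            sg = results[level]
            assert sg.k == 1 and sg.study_ids == (sid,)
            study = fixture_set.subset([sid])[0]
            crude = sm.estimate_effect(sm.make_2x2(study, model))
            assert sg.result.pooled_or == crude.or_
            assert sg.result.ci_low == crude.ci_low
            assert sg.result.ci_high == crude.ci_high

    def test_levels_in_canonical_order(self, fixture_set):
        levels = [sg.level for sg in sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "ethnicity")]
        assert levels == ["Caucasian", "Asian", "African-American", "Mixed"]
        levels = [sg.level for sg in sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "soc")]
        assert levels == ["HB", "PB"]

    def test_per_stratum_selection_can_differ_from_inherited(self, fixture_set):
        # the PB stratum is internally homogeneous under the allele
        # contrast, so re-selecting within the stratum pools fixed while
        # the inherited full-set choice is random
        inherit = {sg.level: sg for sg in sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "soc")}
        per_stratum = {
            sg.level: sg
            for sg in sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "soc", selection="per-stratum")
        }
        assert inherit["PB"].result.model_used is sm.PoolingModel.RANDOM
        assert per_stratum["PB"].result.model_used is sm.PoolingModel.FIXED
        assert inherit["PB"].result.se_log > per_stratum["PB"].result.se_log

    def test_unknown_selection_mode_rejected(self, fixture_set):
        with pytest.raises(sm.ValidationError, match="selection"):
            sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "soc", selection="global")

    def test_unknown_factor_rejected(self, fixture_set):
        with pytest.raises(sm.ValidationError, match="factor"):
            sm.subgroup_analysis(fixture_set, GeneticModel.ALLELE, "genotyping_method")


class TestLeaveOneOut:
    def test_each_row_pools_the_remaining_studies(self, fixture_set):
        rows = sm.leave_one_out(fixture_set, GeneticModel.RECESSIVE)
        assert [r.omitted_study_id for r in rows] == list(fixture_set.ids)
        assert all(r.result.k == len(fixture_set) - 1 for r in rows)

    def test_recessive_conclusion_stable_under_omission(self, fixture_set):
        for row in sm.leave_one_out(fixture_set, GeneticModel.RECESSIVE):
            assert row.result.ci_low > 1.0, row.omitted_study_id

    def test_identical_studies_give_identical_rows(self):
        base = sm.simulate_studies(sm.SimScenario(n_studies=1, seed=3))[0]
        from dataclasses import replace

        studies = sm.StudySet(tuple(replace(base, study_id=f"s{i}") for i in range(3)))
        rows = sm.leave_one_out(studies, GeneticModel.DOMINANT)
        pooled = {(r.result.pooled_log_or, r.result.se_log) for r in rows}
        assert len(pooled) == 1

    def test_omission_stays_within_study_or_range(self, fixture_set):
        effects = [e for _, e in sm.study_effects(fixture_set, GeneticModel.DOMINANT)]
        lo, hi = min(e.log_or for e in effects), max(e.log_or for e in effects)
        for row in sm.leave_one_out(fixture_set, GeneticModel.DOMINANT):
            assert lo - 1e-9 <= row.result.pooled_log_or <= hi + 1e-9

    def test_too_few_studies_rejected(self, two_study_set):
        with pytest.raises(sm.InsufficientStudiesError):
            sm.leave_one_out(two_study_set, GeneticModel.ALLELE)
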