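import json
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpmeta as sm
from snpmeta import GeneticModel, PoolingModel

import _textbook


def _eff(log_or, se):
    return sm.EffectEstimate(log_or=log_or, se=se)


ensembles = st.lists(
    st.tuples(
        st.floats(min_value=-2.0, max_value=2.0),
        st.floats(min_value=0.05, max_value=1.0),
    ),
    min_size=2,
    max_size=12,
)


class TestCochranQ:
    def test_two_study_hand_computation(self):
        q, _, i2 = sm.cochran_q([_eff(0.2, 0.1), _eff(0.4, 0.2)])
        # weights 100 and 25 give mu = 0.24 and Q = 0.8 < df, so I2 truncates
        assert q == pytest.approx(0.8, abs=1e-12)
        assert i2 == 0.0

    def test_widely_separated_effects(self):
        q, p_q, i2 = sm.cochran_q([_eff(0.0, 0.1), _eff(1.0, 0.1)])
        assert q == pytest.approx(50.0, abs=1e-10)
        assert i2 == pytest.approx(98.0, abs=1e-10)
        assert p_q < 1e-10

    def test_identical_effects_are_homogeneous(self):
        q, _, i2 = sm.cochran_q([_eff(0.3, 0.2)] * 5)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(sm.InsufficientStudiesError):
            sm.cochran_q([_eff(0.1, 0.1)])


class TestPoolFixed:
    def test_inverse_variance_hand_computation(self):
        res = sm.pool_fixed([_eff(0.2, 0.1), _eff(0.4, 0.2)])
        assert res.pooled_log_or == pytest.approx(0.24, abs=1e-12)
        assert res.pooled_or == pytest.approx(math.exp(0.24), rel=1e-12)
        assert res.se_log == pytest.approx(1 / math.sqrt(125), rel=1e-12)

    def test_single_study_identity(self):
        res = sm.pool_fixed([_eff(0.3, 0.15)])
        assert res.pooled_log_or == pytest.approx(0.3)
        assert res.se_log == pytest.approx(0.15)
        assert math.isnan(res.p_q)

    def test_replicates_shrink_se_by_sqrt_k(self):
        one = sm.pool_fixed([_eff(0.3, 0.2)])
        four = sm.pool_fixed([_eff(0.3, 0.2)] * 4)
        assert four.pooled_log_or == pytest.approx(one.pooled_log_or)
        assert four.se_log == pytest.approx(one.se_log / 2.0)


class TestPoolRandomDL:
    def test_dl_hand_computation(self):
        res = sm.pool_random_dl([_eff(0.0, 0.1), _eff(1.0, 0.1)])
        assert res.tau2 == pytest.approx(0.49, abs=1e-12)
        assert res.pooled_or == pytest.approx(math.exp(0.5), rel=1e-12)
        assert res.se_log == pytest.approx(0.5, abs=1e-12)
        assert res.ci_low == pytest.approx(math.exp(0.5 - 1.96 * 0.5), rel=1e-9)

    def test_tau2_truncates_to_fixed(self):
        effects = [_eff(0.2, 0.1), _eff(0.4, 0.2)]
        rnd = sm.pool_random_dl(effects)
        fix = sm.pool_fixed(effects)
        assert rnd.tau2 == 0.0
        assert rnd.pooled_log_or == pytest.approx(fix.pooled_log_or, abs=1e-12)
        assert rnd.se_log == pytest.approx(fix.se_log, abs=1e-12)

    def test_homogeneous_effects_reduce_to_fixed(self):
        effects = [_eff(0.3, 0.2)] * 4
        rnd = sm.pool_random_dl(effects)
        assert rnd.tau2 == 0.0
        assert rnd.pooled_log_or == pytest.approx(sm.pool_fixed(effects).pooled_log_or, abs=1e-12)


@pytest.mark.parametrize(
    "p_q,i2,expected",
    [
        (0.05, 30.0, PoolingModel.RANDOM),
        (0.5, 60.0, PoolingModel.RANDOM),
        (0.5, 10.0, PoolingModel.FIXED),
        (0.1, 50.0, PoolingModel.FIXED),  # strict inequalities on both thresholds
    ],
)
def test_select_model_rule(p_q, i2, expected):
    assert sm.select_model(p_q, i2) is expected


class TestAnalyzeFixture:
    @pytest.mark.parametrize(
        "model,or_,lo,hi,i2",
        [
            (GeneticModel.ALLELE, 1.23, 1.13, 1.34, 90.6),
            (GeneticModel.DOMINANT, 1.27, 1.14, 1.41, 86.9),
            (GeneticModel.RECESSIVE, 1.37, 1.21, 1.56, 85.2),
        ],
    )
    def test_pooled_estimates_match_published_values(self, fixture_set, model, or_, lo, hi, i2):
        res = sm.analyze(fixture_set, model)
        assert res.model_used is PoolingModel.RANDOM
        assert res.pooled_or == pytest.approx(or_, abs=0.01)
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)
        assert res.i2 == pytest.approx(i2, abs=0.5)
        assert res.p_value < 0.001
        assert res.p_q < 0.001

    def test_weights_are_normalised(self, fixture_set):
        res = sm.analyze(fixture_set, GeneticModel.DOMINANT)
        assert sum(res.weights) == pytest.approx(1.0, abs=1e-9)


class TestProperties:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(raw=ensembles)
    def test_pooled_mean_in_convex_hull_and_i2_bounded(self, raw):
        effects = [_eff(y, s) for y, s in raw]
        ys = [y for y, _ in raw]
        for res in (sm.pool_fixed(effects), sm.pool_random_dl(effects)):
            assert min(ys) - 1e-9 <= res.pooled_log_or <= max(ys) + 1e-9
            assert 0.0 <= res.i2 < 100.0
            assert res.tau2 >= 0.0
            assert sum(res.weights) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(raw=ensembles, factor=st.floats(min_value=1.1, max_value=5.0))
    def test_fixed_point_estimate_invariant_to_common_se_inflation(self, raw, factor):
        base = sm.pool_fixed([_eff(y, s) for y, s in raw])
        inflated = sm.pool_fixed([_eff(y, s * factor) for y, s in raw])
        assert inflated.pooled_log_or == pytest.approx(base.pooled_log_or, abs=1e-9)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(raw=ensembles)
    def test_agreement_with_textbook_oracle(self, raw):
        effects = [_eff(y, s) for y, s in raw]
        ys = [y for y, _ in raw]
        vs = [s * s for _, s in raw]
        fix = sm.pool_fixed(effects)
        mu, se = _textbook.fixed_pool(ys, vs)
        assert fix.pooled_log_or == pytest.approx(mu, abs=1e-10)
        assert fix.se_log == pytest.approx(se, abs=1e-10)
        assert fix.q == pytest.approx(_textbook.cochran_q(ys, vs), abs=1e-8)
        rnd = sm.pool_random_dl(effects)
        assert rnd.tau2 == pytest.approx(_textbook.dl_tau2(ys, vs), abs=1e-8)
        mu_r, se_r = _textbook.random_pool(ys, vs)
        assert rnd.pooled_log_or == pytest.approx(mu_r, abs=1e-10)
        assert rnd.se_log == pytest.approx(se_r, abs=1e-10)


class TestMetaforCrossCheck:
    """Independent cross-check of the DerSimonian-Laird fit against the R
    package metafor on the bundled dataset (dominant contrast)."""

    def test_dl_fit_matches_metafor(self, fixture_set, tmp_path):
        csv = tmp_path / "studies.csv"
        sm.write_studies(fixture_set, csv)
        script = tmp_path / "dl.R"
        script.write_text(
            """
            suppressMessages(library(metafor))
            suppressMessages(library(jsonlite))
            args <- commandArgs(trailingOnly = TRUE)
            d <- read.csv(args[1])
            es <- escalc(measure = "OR",
                         ai = d$case_ct + d$case_tt, bi = d$case_cc,
                         ci = d$control_ct + d$control_tt, di = d$control_cc)
            fit <- rma(yi, vi, data = es, method = "DL")
            cat(toJSON(list(b = as.numeric(fit$beta), se = fit$se,
                            tau2 = fit$tau2, Q = fit$QE, I2 = fit$I2),
                       digits = 12))
            """,
            encoding="utf-8",
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        )
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
        res = sm.analyze(fixture_set, GeneticModel.DOMINANT)
        assert res.pooled_log_or == pytest.approx(ref["b"], abs=1e-8)
        assert res.se_log == pytest.approx(ref["se"], abs=1e-8)
        assert res.tau2 == pytest.approx(ref["tau2"], abs=1e-8)
        assert res.q == pytest.approx(ref["Q"], abs=1e-6)
        assert res.i2 == pytest.approx(ref["I2"], abs=1e-3)
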