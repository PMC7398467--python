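"""Power, BFDP, Venice grading, classification and validation downgrade."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from gencred import (
    CredibilityConfig, ExternalValidationRecord, VariantKey, apply_validation,
    bfdp, bfdp_grid, classify, expected_se, noteworthiness_threshold,
    statistical_power, venice_grades,
)
from gencred.credibility import (
    FAILED, GENOME_WIDE, LESS_CREDIBLE, NEGATIVE, NOMINAL, NULL, POSITIVE,
    UNTESTED,
)


class TestNoteworthinessThreshold:
    def test_four_to_one_cost_ratio_gives_point_two(self):
        assert noteworthiness_threshold(4.0) == pytest.approx(0.2)

    def test_symmetric_costs_give_half(self):
        assert noteworthiness_threshold(1.0) == pytest.approx(0.5)


class TestStatisticalPower:
    def test_null_effect_recovers_alpha(self):
        for alpha in (0.05, 0.01, 0.2):
            assert statistical_power(0.0, 0.3, alpha) == pytest.approx(alpha)

    def test_effect_at_critical_value_gives_half(self):
        assert statistical_power(1.959964 * 0.1, 0.1) == pytest.approx(
            0.5, abs=1e-4)

    def test_normal_cdf_oracle_at_2p8_sigma(self):
        # Phi(2.8-1.96) + Phi(-2.8-1.96) = Phi(0.84) + Phi(-4.76) ~ 0.7995
        assert statistical_power(0.28, 0.1) == pytest.approx(0.7995, abs=5e-4)

    def test_sign_symmetric(self):
        assert statistical_power(0.3, 0.1) == pytest.approx(
            statistical_power(-0.3, 0.1))


class TestExpectedSe:
    def test_balanced_design_at_half_maf(self):
        # expected allelic cells are all 1000 -> se = sqrt(4/1000)
        se = expected_se(0.5, 1000, 1000, "allelic")
        assert se == pytest.approx(math.sqrt(4 / 1000), rel=1e-12)

    def test_monotone_decreasing_in_maf(self):
        ses = [expected_se(m, 500, 500, "allelic")
               for m in (0.01, 0.05, 0.1, 0.3, 0.5)]
        assert ses == sorted(ses, reverse=True)

    def test_doubling_samples_scales_by_sqrt2(self):
        for model in ("allelic", "dominant", "recessive"):
            se1 = expected_se(0.2, 800, 1200, model)
            se2 = expected_se(0.2, 1600, 2400, model)
            assert se2 == pytest.approx(se1 / math.sqrt(2), rel=1e-12)

    def test_recessive_sparser_than_allelic(self):
        assert expected_se(0.1, 1000, 1000, "recessive") > \
            expected_se(0.1, 1000, 1000, "allelic")


class TestBfdp:
    def test_certain_alternative_gives_zero(self):
        res = bfdp(0.5, 0.01, prior_pi=1.0, W=0.04)
        assert res.bfdp == 0.0

    def test_null_estimate_with_w_equal_v(self):
        res = bfdp(0.0, 0.01, prior_pi=0.5, W=0.01)
        assert res.abf == pytest.approx(math.sqrt(2), rel=1e-12)
        assert res.bfdp == pytest.approx(math.sqrt(2) / (1 + math.sqrt(2)),
                                         rel=1e-12)

    def test_strong_candidate_gene_signal_noteworthy(self):
        W = (math.log(1.5) / 1.959964) ** 2
        res = bfdp(math.log(1.3), 0.05**2, prior_pi=1e-3, W=W)
        assert res.abf == pytest.approx(9.5e-6, rel=0.02)
        assert res.bfdp == pytest.approx(0.0094, abs=3e-4)
        assert res.noteworthy

    def test_vague_prior_effect_limit(self):
        # W -> 0+: ABF -> 1 and BFDP -> 1 - prior_pi
        res = bfdp(0.2, 0.01, prior_pi=0.3, W=1e-12)
        assert res.abf == pytest.approx(1.0, abs=1e-6)
        assert res.bfdp == pytest.approx(0.7, abs=1e-6)

    @given(st.floats(0.0, 1.0), st.floats(0.01, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_decreasing_in_effect_magnitude(self, theta, step):
        v, w, pi = 0.01, 0.04, 0.01
        assert bfdp(theta + step, v, pi, w).bfdp < bfdp(theta, v, pi, w).bfdp

    @given(st.floats(0.001, 0.5), st.floats(0.01, 0.49))
    @settings(max_examples=60, deadline=None)
    def test_nonincreasing_in_prior(self, pi, step):
        v, w = 0.01, 0.04
        hi, lo = pi + step, pi
        assert bfdp(0.2, v, hi, w).bfdp <= bfdp(0.2, v, lo, w).bfdp


class TestBfdpGrid:
    def test_default_grid_has_four_points(self):
        grid = bfdp_grid(0.2, 0.01)
        assert len(grid) == 4
        assert [g.prior_pi for g in grid] == [0.05, 1e-3, 1e-4, 1e-6]

    def test_monotone_across_priors(self):
        grid = bfdp_grid(0.25, 0.01, priors=(0.05, 1e-3))
        assert grid[0].bfdp <= grid[1].bfdp

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            bfdp_grid(0.2, 0.01, priors=())


class TestVeniceGrades:
    @pytest.mark.parametrize("power,i2,amount,replication", [
        (0.84, 53, "A", "C"),   # printed MTHFR allelic row
        (0.60, 40, "B", "B"),
        (0.30, 10, "C", "A"),
        (0.80, 25, "B", "B"),   # boundaries: 0.80 is B, 25 is B
        (0.50, 50, "B", "C"),
        (0.81, 24.9, "A", "A"),
    ])
    def test_grade_boundaries(self, power, i2, amount, replication):
        g = venice_grades(power, i2)
        assert (g.amount, g.replication) == (amount, replication)

    def test_bias_note_reports_egger(self):
        from gencred import EggerResult
        flagged = EggerResult(intercept=1.0, intercept_se=0.2, t_stat=5.0,
                              p_value=0.01, df=5, flagged=True)
        note = venice_grades(0.9, 10, flagged).bias_note
        assert "FLAGGED" in note
        assert "population stratification" in note


class TestClassify:
    def test_mutyh_style_row_is_positive(self):
        # printed row: p = {5.72e-7, 0.019, 6.42e-6}, power 1.00, I2 = 0
        label = classify({"allelic": 5.72e-7, "recessive": 0.019,
                          "dominant": 6.42e-6},
                         bfdp_at_pi005=0.001, power=1.0, i2=0.0,
                         n_cases=28180)
        assert label == POSITIVE

    def test_high_heterogeneity_downgrades_to_less_credible(self):
        # printed 8q24 row: all models significant but I2 = 85
        label = classify({"allelic": 1.75e-5, "recessive": 4.92e-5,
                          "dominant": 2.98e-5},
                         bfdp_at_pi005=0.001, power=1.0, i2=85.0,
                         n_cases=51730)
        assert label == LESS_CREDIBLE

    def test_single_significant_model_is_less_credible(self):
        label = classify({"allelic": 0.01, "recessive": 0.4,
                          "dominant": 0.2},
                         bfdp_at_pi005=0.001, power=0.95, i2=0.0,
                         n_cases=20000)
        assert label == LESS_CREDIBLE

    def test_nonsignificant_small_sample_is_negative(self):
        label = classify({"allelic": 0.4, "recessive": 0.6, "dominant": 0.5},
                         bfdp_at_pi005=0.9, power=0.3, i2=0.0, n_cases=4017)
        assert label == NEGATIVE

    def test_nonsignificant_large_sample_is_null(self):
        label = classify({"allelic": 0.4, "recessive": 0.6, "dominant": 0.5},
                         bfdp_at_pi005=0.9, power=0.3, i2=0.0, n_cases=6000)
        assert label == NULL

    def test_high_bfdp_blocks_positive(self):
        label = classify({"allelic": 0.01, "recessive": 0.02,
                          "dominant": 0.03},
                         bfdp_at_pi005=0.5, power=0.95, i2=10.0,
                         n_cases=20000)
        assert label == LESS_CREDIBLE

    def test_two_available_models_can_still_be_positive(self):
        # recessive model structurally missing (rare homozygotes)
        label = classify({"allelic": 1e-6, "dominant": 1e-4},
                         bfdp_at_pi005=0.01, power=0.99, i2=5.0,
                         n_cases=28302)
        assert label == POSITIVE

    @given(ps=st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=3),
           b=st.floats(0, 1), power=st.floats(0, 1),
           i2=st.floats(0, 100), n=st.integers(0, 100000))
    @settings(max_examples=100, deadline=None)
    def test_total_and_single_valued(self, ps, b, power, i2, n):
        labels = {"allelic": ps[0]}
        for name, p in zip(("recessive", "dominant"), ps[1:]):
            labels[name] = p
        out = classify(labels, b, power, i2, n)
        assert out in {POSITIVE, LESS_CREDIBLE, NULL, NEGATIVE}


class TestApplyValidation:
    def _ext(self, **kw):
        defaults = dict(variant=VariantKey(gene="G", variant_id="rs1"),
                        imputation_ok=True, n_cases=58131, n_controls=67347)
        defaults.update(kw)
        return ExternalValidationRecord(**defaults)

    def test_failed_validation_downgrades_positive(self):
        label, status = apply_validation(
            POSITIVE, self._ext(p_additive=0.3, p_dominant=0.6))
        assert (label, status) == (LESS_CREDIBLE, FAILED)

    def test_genome_wide_validation_keeps_positive(self):
        label, status = apply_validation(POSITIVE, self._ext(p_additive=1e-9))
        assert (label, status) == (POSITIVE, GENOME_WIDE)

    def test_nominal_validation_keeps_positive(self):
        label, status = apply_validation(POSITIVE, self._ext(p_additive=0.01))
        assert (label, status) == (POSITIVE, NOMINAL)

    def test_poor_imputation_leaves_untested(self):
        label, status = apply_validation(
            POSITIVE, self._ext(imputation_ok=False))
        assert (label, status) == (POSITIVE, UNTESTED)

    def test_missing_record_leaves_untested(self):
        label, status = apply_validation(POSITIVE, None)
        assert (label, status) == (POSITIVE, UNTESTED)

    def test_failed_validation_leaves_less_credible_unchanged(self):
        label, status = apply_validation(
            LESS_CREDIBLE, self._ext(p_additive=0.9))
        assert (label, status) == (LESS_CREDIBLE, FAILED)

    def test_null_label_never_downgraded(self):
        label, status = apply_validation(NULL, self._ext(p_additive=0.9))
        assert (label, status) == (NULL, FAILED)
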