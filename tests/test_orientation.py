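"""Score calibration, lever-rule unmixing, ANOVA and regime segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from igg_orient.orientation import (
    MixtureEndmembers,
    SampleRecord,
    anova_oneway,
    calibrate,
    fit_endmembers,
    forward_mixture,
    invert_mixture,
    score_to_ffc,
    segment_regimes,
)


class TestCalibration:
    def test_anchor_reproduction(self):
        cal = calibrate(-1.0, 1.0)
        assert cal.slope == pytest.approx(0.03)
        assert cal.intercept == pytest.approx(0.31)
        assert score_to_ffc(cal, -1.0) == pytest.approx(0.28)
        assert score_to_ffc(cal, 1.0) == pytest.approx(0.34)
        assert score_to_ffc(cal, 0.0) == pytest.approx(0.31)

    def test_unit_slope_construction(self):
        cal = calibrate(0.0, 0.06)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.28)

    @settings(derandomize=True, max_examples=50)
    @given(
        s_flat=st.floats(-10, 10),
        delta=st.floats(0.01, 10),
        alpha=st.floats(0, 1),
    )
    def test_affine_property_and_rescaling_invariance(self, s_flat, delta, alpha):
        s_side = s_flat + delta
        cal = calibrate(s_flat, s_side)
        # anchors exact for arbitrary anchor scores
        assert score_to_ffc(cal, s_flat) == pytest.approx(0.28, abs=1e-12)
        assert score_to_ffc(cal, s_side) == pytest.approx(0.34, abs=1e-12)
        # affine interpolation
        s = alpha * s_flat + (1 - alpha) * s_side
        f = alpha * 0.28 + (1 - alpha) * 0.34
        assert score_to_ffc(cal, s) == pytest.approx(f, abs=1e-9)
        # rescaling the score axis and recalibrating yields identical f_Fc
        cal2 = calibrate(2.0 * s_flat + 5.0, 2.0 * s_side + 5.0)
        assert score_to_ffc(cal2, 2.0 * s + 5.0) == pytest.approx(f, abs=1e-9)

    def test_equal_anchor_scores_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            calibrate(0.5, 0.5)


class TestMixture:
    def test_nhs_silane_pair(self):
        em = MixtureEndmembers(h=0.5, t=0.0)
        p = invert_mixture(0.25, em)
        assert p == pytest.approx(0.5)          # head:tail = 1:1
        assert forward_mixture(0.5, em) == pytest.approx(0.25)

    def test_endmember_identities(self):
        em = MixtureEndmembers(h=0.5, t=0.0)
        assert invert_mixture(0.5, em) == 1.0
        assert invert_mixture(0.0, em) == 0.0

    def test_lever_rule_arithmetic(self):
        em = MixtureEndmembers(h=0.5, t=0.0)
        assert invert_mixture(0.3, em) == pytest.approx(0.6)
        assert forward_mixture(0.75, em) == pytest.approx(0.375)

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(0, 1), h=st.floats(0.2, 1.0), t=st.floats(0.0, 0.1))
    def test_forward_invert_inverse(self, p, h, t):
        em = MixtureEndmembers(h=h, t=t)
        assert invert_mixture(forward_mixture(p, em), em) == pytest.approx(
            p, abs=1e-9
        )

    def test_out_of_gamut_diagnostic(self):
        em = MixtureEndmembers(h=0.5, t=0.1)
        with pytest.raises(ValueError, match="0.6.*0.1.*0.5"):
            invert_mixture(0.6, em)

    def test_degenerate_endmembers_rejected(self):
        with pytest.raises(ValueError):
            MixtureEndmembers(h=0.3, t=0.3)

    def test_fit_endmembers_recovers_exact_pairs(self):
        em = MixtureEndmembers(h=0.5, t=0.05)
        pairs = [(p, forward_mixture(p, em)) for p in (0.2, 0.5, 0.9)]
        fitted = fit_endmembers(pairs)
        assert fitted.h == pytest.approx(0.5, abs=1e-9)
        assert fitted.t == pytest.approx(0.05, abs=1e-9)

    def test_fit_endmembers_pins_negative_tail_at_zero(self):
        # the three reported (proportion, f_Fc) pairs are not jointly
        # consistent with any t >= 0 lever rule; the constrained fit pins t=0
        pairs = [(4 / 7, 0.3), (0.5, 0.25), (0.75, 0.4)]
        fitted = fit_endmembers(pairs)
        assert fitted.t == 0.0
        assert 0.4 < fitted.h < 0.6


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        F, p = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert F == 0.0
        assert p == 1.0

    def test_zero_within_variance_gives_infinite_f(self):
        F, p = anova_oneway([[0.0, 0.0], [1.0, 1.0]])
        assert F == np.inf
        assert p == 0.0

    def test_hand_computed_sums_of_squares(self):
        groups = [[1.0, 2.0], [4.0, 5.0], [7.0, 9.0]]
        # grand mean 28/6; SSB = 2[(1.5-g)^2+(4.5-g)^2+(8-g)^2], SSW = 0.5+0.5+2
        g = 28.0 / 6.0
        ssb = 2 * ((1.5 - g) ** 2 + (4.5 - g) ** 2 + (8.0 - g) ** 2)
        ssw = 3.0
        expected_f = (ssb / 2) / (ssw / 3)
        F, p = anova_oneway(groups)
        assert F == pytest.approx(expected_f, rel=1e-12)
        assert p == pytest.approx(float(stats.f.sf(expected_f, 2, 3)), rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, size=6) for m in (0.0, 0.5, 2.0)]
        F, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            anova_oneway([[1.0], [2.0, 3.0]])


def _records(gammas, scores):
    return [
        SampleRecord(sample_id=f"s{i}", gamma=g, d_nm=g / 1.216, score=s)
        for i, (g, s) in enumerate(zip(gammas, scores))
    ]


class TestSegmentation:
    def test_noiseless_steps_recovered_exactly(self):
        gammas = np.linspace(0.2, 3.4, 12)
        scores = [0.0] * 4 + [0.06] * 4 + [-0.01] * 4
        seg = segment_regimes(_records(gammas, scores))
        assert seg.significant
        assert seg.f_statistic == np.inf and seg.p_value == 0.0
        assert seg.breakpoints == (4, 8)
        b1, b2 = seg.boundaries
        assert b1 == pytest.approx((gammas[3] + gammas[4]) / 2)
        assert b2 == pytest.approx((gammas[7] + gammas[8]) / 2)
        assert seg.assignment == ["flat_on"] * 4 + ["side_on"] * 4 + ["vertical"] * 4

    def test_constant_scores_not_significant(self):
        gammas = np.linspace(0.2, 3.4, 9)
        seg = segment_regimes(_records(gammas, [0.5] * 9))
        assert not seg.significant
        assert seg.boundaries is None

    def test_noisy_steps_within_one_grid_spacing(self):
        gammas = np.linspace(0.2, 3.4, 18)
        step = gammas[1] - gammas[0]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = np.where(
                gammas < 0.8, 0.0, np.where(gammas < 2.2, 0.06, -0.01)
            ) * rng.lognormal(0.0, 0.05, size=len(gammas))
            seg = segment_regimes(_records(gammas, scores))
            if seg.significant:
                b1, b2 = seg.boundaries
                if abs(b1 - 0.8) <= step and abs(b2 - 2.2) <= step:
                    hits += 1
        assert hits >= 18

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            segment_regimes(_records([0.1, 0.2, 0.3], [0.0, 0.1, 0.2]))

    def test_flat_vertical_coincidence_still_significant(self):
        # vertical level equal to flat-on level: only the transitions count
        gammas = np.linspace(0.2, 3.4, 12)
        rng = np.random.default_rng(1)
        scores = np.array([0.0] * 4 + [0.06] * 4 + [0.0] * 4)
        scores += rng.normal(0.0, 1e-3, size=12)
        seg = segment_regimes(_records(gammas, scores))
        assert seg.significant
        assert seg.pairwise_p["flat_on|vertical"] > 0.05  # reported, not gated
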