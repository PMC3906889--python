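"""Dose-response interaction scoring, classification, ranking, and QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qhtcp.interaction import (
    DELETION_ENHANCER,
    DELETION_SUPPRESSOR,
    NO_INTERACTION,
    DoseLadderError,
    DoseResponse,
    QCConfig,
    Thresholds,
    WILDTYPE_THRESHOLDS,
    build_reference,
    classify,
    gene_drug_score,
    overlap_orf_correlation,
    qc_flags,
    rank_interactions,
    score_interaction,
)

DOSES = np.array([0.0, 0.05, 0.10, 0.15, 0.20, 0.25])


def flat_reference(level=30.0, doses=DOSES):
    return build_reference({float(d): [level, level, level] for d in doses})


def make_dr(strain_id, L_values, doses=DOSES):
    L = np.asarray(L_values, dtype=float)
    return DoseResponse(strain_id, doses, L, ~np.isnan(L))


def quadratic_dr(strain_id, K0, B, C, ref_level=30.0, doses=DOSES, censor_from=None):
    L = ref_level + K0 + B * doses + C * doses**2
    if censor_from is not None:
        L = np.where(doses >= censor_from, np.nan, L)
    return make_dr(strain_id, L, doses)


class TestBuildReference:
    def test_constant_replicates_give_degenerate_band(self):
        ref = build_reference({0.0: [30.0] * 5, 0.1: [30.0] * 5})
        assert np.all(ref.central == 30.0)
        assert np.all(ref.band_low == 30.0) and np.all(ref.band_high == 30.0)

    def test_normal_replicates_match_empirical_quantiles(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(30.0, 2.0, 768)
        ref = build_reference({0.0: draws, 0.05: draws})
        assert abs(ref.central[0] - 30.0) < 0.3
        assert abs(ref.band_low[0] - 26.08) < 0.3
        assert abs(ref.band_high[0] - 33.92) < 0.3
        # oracle: the same draws summarized independently
        assert ref.central[0] == np.median(draws)
        assert ref.band_low[0] == np.percentile(draws, 2.5)

    def test_censored_replicates_excluded(self):
        vals = [28.0, 30.0, 32.0, np.nan, np.nan, np.nan]
        ref = build_reference({0.0: vals})
        assert ref.central[0] == 30.0
        assert ref.n_replicates[0] == 3

    def test_mean_statistic_available(self):
        ref = build_reference({0.0: [10.0, 20.0, 60.0]}, stat="mean")
        assert ref.central[0] == pytest.approx(30.0)

    def test_too_few_grown_replicates_names_dose(self):
        with pytest.raises(DoseLadderError, match="0.1"):
            build_reference({0.0: [30.0, 31.0], 0.1: [30.0, np.nan]})


class TestScoreInteraction:
    def test_adjusted_response_is_exactly_zero_at_dose_zero(self, small_screen):
        ref = build_reference(small_screen.reference_L_by_dose)
        for dr in small_screen.dose_responses.values():
            res = score_interaction(dr, ref)
            assert res.L_adj[0] == 0.0

    def test_reference_scores_zero_against_itself(self):
        ref = flat_reference()
        dr = make_dr("self", np.full(6, 30.0))
        res = score_interaction(dr, ref)
        assert res.K0 == pytest.approx(0.0, abs=1e-9)
        assert res.INT == pytest.approx(0.0, abs=1e-9)

    def test_planted_quadratic_recovered_exactly(self):
        """Planted response RD + 5 + 40 D - 80 D^2: coefficients and the
        interaction value at the top dose come back exactly (direct
        polynomial evaluation is the oracle)."""
        res = score_interaction(quadratic_dr("g", 5.0, 40.0, -80.0), flat_reference())
        assert res.K0 == pytest.approx(5.0, abs=1e-9)
        assert res.B == pytest.approx(40.0, abs=1e-6)
        assert res.C == pytest.approx(-80.0, abs=1e-6)
        assert res.D_max_scored == 0.25
        assert res.INT == pytest.approx(40 * 0.25 - 80 * 0.25**2, abs=1e-6)
        assert res.INT == pytest.approx(5.0, abs=1e-6)
        assert res.tier == 0

    def test_censored_doses_shift_d_max_and_set_tier(self):
        res = score_interaction(
            quadratic_dr("g", 5.0, 40.0, -80.0, censor_from=0.20), flat_reference()
        )
        assert res.tier == 2
        assert res.D_max_scored == 0.15
        assert res.INT == pytest.approx(40 * 0.15 - 80 * 0.15**2, abs=1e-6)
        assert res.INT == pytest.approx(4.2, abs=1e-6)

    def test_fewer_than_three_grown_doses_gives_na_int(self):
        res = score_interaction(
            quadratic_dr("g", 0.0, 40.0, 0.0, censor_from=0.10), flat_reference()
        )
        assert math.isnan(res.INT)
        assert res.tier == 4

    def test_no_growth_at_dose_zero_is_an_error(self):
        L = np.array([np.nan, 31.0, 32.0, 33.0, 34.0, 35.0])
        with pytest.raises(DoseLadderError, match="dose 0"):
            score_interaction(make_dr("g", L), flat_reference())

    def test_mismatched_ladder_rejected(self):
        dr = quadratic_dr("g", 0.0, 0.0, 0.0, doses=np.array([0, 0.1, 0.2, 0.3, 0.4, 0.5]))
        with pytest.raises(DoseLadderError):
            score_interaction(dr, flat_reference())

    def test_int_invariant_to_constant_shift(self):
        """A constant shift of the whole response is absorbed into K0."""
        ref = flat_reference()
        r1 = score_interaction(quadratic_dr("a", 2.0, 30.0, -40.0), ref)
        r2 = score_interaction(quadratic_dr("b", 9.0, 30.0, -40.0), ref)
        assert r2.INT == pytest.approx(r1.INT, abs=1e-9)
        assert r2.K0 - r1.K0 == pytest.approx(7.0, abs=1e-9)

    @given(
        delta=st.floats(0.0, 50.0),
        gamma=st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_added_dose_terms(self, delta, gamma):
        """Adding delta*D + gamma*D^2 (not both zero) strictly increases
        the interaction value."""
        if delta + gamma < 1e-3:  # below numerical resolution of the fit
            return
        ref = flat_reference()
        base = score_interaction(quadratic_dr("a", 1.0, 10.0, -20.0), ref)
        bumped = score_interaction(
            quadratic_dr("b", 1.0, 10.0 + delta, -20.0 + gamma), ref
        )
        assert bumped.INT > base.INT


class TestClassify:
    @pytest.mark.parametrize(
        "INT, th, expected",
        [
            (10.5, Thresholds(10, -16), DELETION_ENHANCER),
            (-16.0, Thresholds(10, -16), NO_INTERACTION),  # strict boundary
            (10.0, Thresholds(10, -16), NO_INTERACTION),
            (-12.5, WILDTYPE_THRESHOLDS, DELETION_SUPPRESSOR),
            (-17.0, Thresholds(10, -16), DELETION_SUPPRESSOR),
            (0.0, Thresholds(10, -16), NO_INTERACTION),
        ],
    )
    def test_threshold_calls(self, INT, th, expected):
        res = score_interaction(
            quadratic_dr("g", 0.0, INT / 0.25, 0.0), flat_reference()
        )
        assert res.INT == pytest.approx(INT, abs=1e-9)
        assert classify(res, th) == expected

    def test_unscoreable_no_growth_strain_is_tiered_enhancer(self):
        res = score_interaction(
            quadratic_dr("g", 0.0, 200.0, 0.0, censor_from=0.10), flat_reference()
        )
        assert math.isnan(res.INT) and res.tier > 0
        assert classify(res) == DELETION_ENHANCER


class TestRanking:
    def test_tier_dominates_int(self):
        ref = flat_reference()
        tiered = score_interaction(quadratic_dr("t", 0, 20, -30, censor_from=0.20), ref)
        strong = score_interaction(quadratic_dr("s", 0, 200, 0), ref)
        order = rank_interactions([strong, tiered])
        assert [r.strain_id for r in order] == ["t", "s"]

    def test_matches_brute_force_sort(self, small_screen):
        ref = build_reference(small_screen.reference_L_by_dose)
        results = [
            score_interaction(dr, ref) for dr in small_screen.dose_responses.values()
        ]
        ranked = [r.strain_id for r in rank_interactions(results)]
        brute = sorted(
            results,
            key=lambda r: (
                -r.tier,
                -(math.inf if math.isnan(r.INT) else r.INT),
                r.strain_id,
            ),
        )
        assert ranked == [r.strain_id for r in brute]
        # ties by id are deterministic: re-running gives the same order
        assert ranked == [r.strain_id for r in rank_interactions(results[::-1])]


class TestGeneDrugScore:
    def test_identical_strains_score_zero(self):
        assert gene_drug_score(35.0, 30.0, 35.0, 30.0) == 0.0

    def test_hand_computed_example(self):
        # +3 h vs reference on control media, +8 h on the drug -> 5 h
        assert gene_drug_score(38.0, 33.0, 30.0, 30.0) == pytest.approx(5.0)

    def test_antisymmetric_in_roles(self):
        s = gene_drug_score(38.0, 33.0, 30.0, 31.0)
        assert gene_drug_score(30.0, 31.0, 38.0, 33.0) == pytest.approx(-s)

    def test_no_growth_propagates_na(self):
        assert math.isnan(gene_drug_score(float("nan"), 33.0, 30.0, 31.0))


class TestOverlapCorrelation:
    def _result(self, strain_id, INT):
        return score_interaction(
            quadratic_dr(strain_id, 0.0, INT / 0.25, 0.0), flat_reference()
        )

    def test_identical_pairs_correlate_perfectly(self):
        pairs = [
            (self._result(f"a{i}", v), self._result(f"b{i}", v))
            for i, v in enumerate([3.0, -10.0, 25.0, 0.5])
        ]
        r, table = overlap_orf_correlation(pairs)
        assert r == pytest.approx(1.0)
        assert len(table) == 4

    def test_shared_effect_pairs_correlate(self):
        rng = np.random.default_rng(8)
        shared = rng.normal(0.0, 15.0, 50)
        pairs = [
            (
                self._result(f"a{i}", s + rng.normal(0, 1.0)),
                self._result(f"b{i}", s + rng.normal(0, 1.0)),
            )
            for i, s in enumerate(shared)
        ]
        r, _ = overlap_orf_correlation(pairs)
        assert r > 0.8

    def test_independent_pairs_do_not_correlate(self):
        rng = np.random.default_rng(9)
        pairs = [
            (
                self._result(f"a{i}", rng.normal(0, 10)),
                self._result(f"b{i}", rng.normal(0, 10)),
            )
            for i in range(100)
        ]
        r, _ = overlap_orf_correlation(pairs)
        assert abs(r) < 0.3

    def test_too_few_complete_pairs_rejected(self):
        pairs = [(self._result("a", 1.0), self._result("b", 2.0))] * 2
        with pytest.raises(ValueError):
            overlap_orf_correlation(pairs)


class TestQcFlags:
    def test_clean_quadratic_has_no_flags(self):
        res = score_interaction(quadratic_dr("g", 0.0, 100.0, -80.0), flat_reference())
        assert qc_flags(res) == frozenset()

    def test_large_zero_dose_effect(self):
        res = score_interaction(quadratic_dr("g", 25.0, 100.0, -80.0), flat_reference())
        assert "large_zero_dose_effect" in qc_flags(res, cfg=QCConfig(k0_cut=10.0))

    def test_plateau_response_flagged(self):
        """Rising then flat response with a large INT: the fitted slope at
        D_max (B + 2 C D_max) is near zero."""
        res = score_interaction(quadratic_dr("g", 0.0, 160.0, -320.0), flat_reference())
        slope = res.B + 2 * res.C * res.D_max_scored
        assert abs(slope) < 5.0 and abs(res.INT) >= 10.0
        assert "plateau_response" in qc_flags(res)

    def test_wildtype_context_interaction(self):
        res = score_interaction(quadratic_dr("g", 0.0, 100.0, -80.0), flat_reference())
        companion = score_interaction(quadratic_dr("g", 0.0, 80.0, 0.0), flat_reference())
        assert "wildtype_context_interaction" in qc_flags(res, companion=companion)
        quiet = score_interaction(quadratic_dr("g", 0.0, 4.0, 0.0), flat_reference())
        assert "wildtype_context_interaction" not in qc_flags(res, companion=quiet)

    def test_weak_effect_flagged(self):
        res = score_interaction(quadratic_dr("g", 0.0, 8.0, 0.0), flat_reference())
        assert "weak_effect" in qc_flags(res)

    def test_poor_quadratic_fit_flagged(self):
        L = 30.0 + np.array([0.0, 20.0, -15.0, 25.0, -20.0, 15.0])
        res = score_interaction(make_dr("g", L), flat_reference())
        assert res.quad_r2 < 0.8
        assert "poor_quadratic_fit" in qc_flags(res)
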