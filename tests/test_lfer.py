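"""Linear free-energy fits: Hammett, Yukawa-Tsuno, Mayr-Patz, and the
sigma+ predictive model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleokin import lfer
from nucleokin.records import ElectrophileRecord

SIGMA = np.array([-0.27, -0.17, 0.0, 0.06, 0.23, 0.54, 0.66, 0.78])
SIGMA_PLUS = np.array([-0.78, -0.31, 0.0, -0.07, 0.11, 0.61, 0.66, 0.79])


def _avg_log_k1(table1):
    return [lfer.average_log_rate(r) for r in table1]


class TestAverageLogRate:
    def test_mean_over_both_ph(self, table1_by_label):
        assert lfer.average_log_rate(table1_by_label["7c"]) == pytest.approx(
            (math.log10(427) + math.log10(465)) / 2, abs=1e-12
        )
        assert lfer.average_log_rate(table1_by_label["7c"]) == pytest.approx(2.649, abs=1e-3)
        assert lfer.average_log_rate(table1_by_label["7a"]) == pytest.approx(1.143, abs=1e-3)

    def test_single_ph_record(self):
        rec = ElectrophileRecord(label="x", substituent="H", k_pH2=1.0, k1_pH2=100.0)
        assert lfer.average_log_rate(rec) == pytest.approx(2.0)

    def test_no_k1_rejected(self):
        rec = ElectrophileRecord(label="x", substituent="H")
        with pytest.raises(ValueError, match="no k1"):
            lfer.average_log_rate(rec)


class TestHammett:
    def test_identity_line(self):
        fit = lfer.hammett_fit([-0.3, 0.0, 0.5], [-0.3, 0.0, 0.5])
        assert fit.rho == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-14)
        assert fit.r2 == pytest.approx(1.0)

    def test_sigma_plus_fit_matches_published(self, table1):
        fit = lfer.hammett_fit(_avg_log_k1(table1), SIGMA_PLUS, scale="sigma_plus")
        assert round(fit.rho, 2) == 2.48
        assert round(fit.intercept, 2) == 2.91

    def test_resonance_scale_fits_better(self, table1):
        y = _avg_log_k1(table1)
        r2_plus = lfer.hammett_fit(y, SIGMA_PLUS).r2
        r2_plain = lfer.hammett_fit(y, SIGMA).r2
        assert r2_plus > r2_plain

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lfer.hammett_fit([1.0, 2.0, 3.0], [0.0, 0.1])


class TestYukawaTsuno:
    @staticmethod
    def _synthetic(rho, r, intercept, sigma=SIGMA, sigma_plus=SIGMA_PLUS):
        return intercept + rho * (sigma + r * (sigma_plus - sigma))

    @pytest.mark.parametrize("method", ["joint-bilinear", "grid-conditional"])
    def test_exact_recovery_on_noiseless_data(self, method):
        y = self._synthetic(2.0, 1.5, 3.0)
        fit = lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA_PLUS, method=method)
        assert fit.rho == pytest.approx(2.0, rel=1e-6)
        assert fit.r == pytest.approx(1.5, rel=1e-6 if method == "joint-bilinear" else 1e-2)
        assert fit.intercept == pytest.approx(3.0, rel=1e-6)

    def test_degenerate_scales(self):
        y = 1.0 + 2.0 * SIGMA
        with pytest.raises(ValueError, match="undefined"):
            lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA, method="joint-bilinear")
        fit = lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA, method="grid-conditional")
        assert not fit.r_identifiable
        assert fit.rho == pytest.approx(2.0)

    def test_r_limits_reduce_to_single_scale_fits(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.05, len(SIGMA))
        for r_true, scale in ((0.0, SIGMA), (1.0, SIGMA_PLUS)):
            y = self._synthetic(2.2, r_true, 1.0) + noise
            h = lfer.hammett_fit(y, scale)
            yt = lfer.yukawa_tsuno_fit(
                y, SIGMA, SIGMA_PLUS, method="grid-conditional", grid=(r_true, r_true, 1.0)
            )
            assert yt.rho == pytest.approx(h.rho, rel=1e-9)
            assert yt.intercept == pytest.approx(h.intercept, rel=1e-9)

    def test_joint_fit_beats_conditional_grid(self, table1):
        y = _avg_log_k1(table1)
        joint = lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA_PLUS, method="joint-bilinear")
        grid = lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA_PLUS, method="grid-conditional")
        assert joint.sse <= grid.sse + 1e-12

    def test_joint_fit_is_global_optimum_on_brute_force_grid(self, table1):
        # oracle: exhaustive 200 x 200 scan over (rho, r) with the optimal
        # intercept at each node
        y = np.asarray(_avg_log_k1(table1))
        joint = lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA_PLUS)
        best = np.inf
        for rho in np.linspace(0.0, 5.0, 200):
            for r in np.linspace(-1.0, 3.0, 200):
                x = SIGMA + r * (SIGMA_PLUS - SIGMA)
                resid = (y - y.mean()) - rho * (x - x.mean())
                best = min(best, float(np.sum(resid**2)))
        assert joint.sse <= best + 1e-12

    def test_effective_constant_reproduces_fit(self, table1):
        # re-regressing log k1 on sigma_eff = sigma + r (sigma+ - sigma)
        # returns the same (rho, intercept)
        y = _avg_log_k1(table1)
        fit = lfer.yukawa_tsuno_fit(y, SIGMA, SIGMA_PLUS)
        sigma_eff = SIGMA + fit.r * (SIGMA_PLUS - SIGMA)
        h = lfer.hammett_fit(y, sigma_eff)
        assert h.rho == pytest.approx(fit.rho, rel=1e-9)
        assert h.intercept == pytest.approx(fit.intercept, rel=1e-9)


class TestMayrFit:
    def test_published_parameters(self, table1):
        with_E = [r for r in table1 if r.E is not None]
        fit = lfer.mayr_fit(
            [lfer.average_log_rate(r) for r in with_E], [r.E for r in with_E]
        )
        assert fit.n_points == 7
        assert round(fit.s_N, 2) == 1.18
        assert round(fit.N, 2) == 9.37
        assert round(fit.intercept, 2) == 11.06

    def test_constructed_line(self):
        E = [-8.0, -6.0, -4.0]
        fit = lfer.mayr_fit([1.0 * (e + 8.0) for e in E], E)
        assert fit.s_N == pytest.approx(1.0)
        assert fit.N == pytest.approx(8.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_inverted_scale_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            lfer.mayr_fit([3.0, 2.0, 1.0], [-8.0, -6.0, -4.0])

    @pytest.mark.parametrize("N_true", [5.0, 9.37, 12.0])
    @pytest.mark.parametrize("sN_true", [0.8, 1.18, 1.3])
    def test_noiseless_generation_inverts_exactly(self, N_true, sN_true):
        E = np.array([-8.4, -7.7, -7.2, -6.7, -5.7, -5.5, -5.1])
        log_k = sN_true * (E + N_true)
        fit = lfer.mayr_fit(log_k, E)
        assert fit.s_N == pytest.approx(sN_true, rel=1e-9)
        assert fit.N == pytest.approx(N_true, rel=1e-9)


class TestSingleRateEstimates:
    @pytest.mark.parametrize(
        "k, expected",
        [(3.37e4, 9.59), (1.00e2, 7.06), (2.40e4, 9.44), (5.55e2, 7.80)],
    )
    def test_against_reference_electrophile(self, k, expected):
        assert round(lfer.n_from_single_rate(k, E=-5.06), 2) == expected

    def test_unit_rate_zero_electrophilicity(self):
        assert lfer.n_from_single_rate(1.0, 0.0) == 0.0

    @given(
        N=st.floats(0.0, 15.0),
        E=st.floats(-12.0, 0.0),
        sN=st.floats(0.6, 1.4),
    )
    @settings(derandomize=True, deadline=None)
    def test_round_trip_with_rate_prediction(self, N, E, sN):
        k = lfer.predict_rate(N, sN, E)
        assert lfer.n_from_single_rate(k, E, s_N=sN) == pytest.approx(N, abs=1e-9)


class TestSigmaPlusModel:
    MODEL = lfer.fit_sigma_plus_model([9.37, 10.47, 10.02], [-1.30, -1.81, -1.70])

    def test_published_coefficients(self):
        assert round(self.MODEL.slope, 2) == -2.01
        assert round(self.MODEL.intercept, 2) == 6.72

    def test_identity(self):
        fit = lfer.fit_sigma_plus_model([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-14)

    def test_coincident_points_still_fit(self):
        fit = lfer.fit_sigma_plus_model([1.0, 1.2, 3.0], [0.0, 0.0, 1.0])
        assert np.isfinite(fit.slope)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            lfer.fit_sigma_plus_model([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    @pytest.mark.parametrize(
        "sigma_plus, expected", [(-0.78, 8.29), (-0.31, 7.34), (0.0, 6.72)]
    )
    def test_predictions_at_published_precision(self, sigma_plus, expected):
        assert round(lfer.predict_N(self.MODEL, sigma_plus), 2) == expected

    def test_unrounded_evaluation_available(self):
        n = lfer.predict_N(self.MODEL, -0.78, coefficient_precision=None)
        assert n == pytest.approx(self.MODEL.intercept + self.MODEL.slope * -0.78)
        assert n != lfer.predict_N(self.MODEL, -0.78)


class TestRatePrediction:
    @pytest.mark.parametrize(
        "N, E, expected",
        [(8.29, -9.56, 5.37e-2), (7.34, -9.56, 6.03e-3), (0.0, 0.0, 1.0)],
    )
    def test_predict_rate(self, N, E, expected):
        assert lfer.predict_rate(N, 1.0, E) == pytest.approx(expected, rel=2e-3)

    def test_validation_ratios_and_flag(self):
        records, within = lfer.validate_predictions(
            [4.51e-1, 9.38e-2], [5.37e-2, 6.03e-3], names=["15", "16"]
        )
        assert round(records[0].ratio, 1) == 8.4
        assert round(records[1].ratio, 1) == 15.6
        assert within

    def test_reciprocal_deviation_counts(self):
        _, within = lfer.validate_predictions([1.0], [500.0])
        assert not within

    def test_equal_pair(self):
        records, within = lfer.validate_predictions([2.0], [2.0])
        assert records[0].ratio == 1.0 and within

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            lfer.validate_predictions([1.0], [0.0])


class TestTableMonotonicity:
    def test_reactivity_increases_with_sigma_p_and_E(self, table1):
        # strict monotonicity holds in sigma_p and in E; the sigma+ ordering
        # is broken once, by the fluoro electrophile (sigma+ = -0.07 yet more
        # reactive than the unsubstituted one)
        recs = sorted(table1, key=lambda r: r.sigma_p)
        logs = [lfer.average_log_rate(r) for r in recs]
        assert np.all(np.diff(logs) > 0)
        recs_E = sorted((r for r in table1 if r.E is not None), key=lambda r: r.E)
        logs_E = [lfer.average_log_rate(r) for r in recs_E]
        assert np.all(np.diff(logs_E) > 0)
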