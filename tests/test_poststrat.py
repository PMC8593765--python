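"""Poststratification oracles, CI properties, economic summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from censusmrp import (
    ModelConfig,
    aggregate_excess,
    aggregate_excess_log_odds,
    age_specific_excess,
    economic_summary,
    sensitivity_windows,
)
from censusmrp.constants import AGE_BIN_LABELS, N_MONTHS
from censusmrp.model import PosteriorDraws, full_grid_cells
from censusmrp.poststrat import AggregationError, _weight_array
from censusmrp.strata import cell_id


def make_weights(w_array):
    """Weight table from a (9, 2, 3) array."""
    rows = []
    for a in range(9):
        for s in range(2):
            for e in range(3):
                rows.append({
                    "age_bin": AGE_BIN_LABELS[a], "age_bin_index": a,
                    "sex": "male" if s else "female", "sex_index": s,
                    "education": e, "weight": w_array[a, s, e],
                    "count": 0})
    return pd.DataFrame(rows)


def make_draws(p, onset=14, seed=0):
    """PosteriorDraws with given per-cell probabilities (n_draws, 1188)."""
    p = np.asarray(p, float)
    cfg = ModelConfig(onset_month=onset, n_chains=2, n_draws=100, seed=seed)
    return PosteriorDraws(
        theta=np.zeros((2, p.shape[0] // 2, 1)),
        beta=np.zeros((p.shape[0], 1)), p=p, cells=full_grid_cells(),
        coef_names=["mu[0]"], param_names=["mu[0]"],
        diagnostics={"max_split_rhat": 1.0, "min_bulk_ess": 1000.0,
                     "divergences": 0, "rhat_defined": True,
                     "converged": True}, config=cfg)


def grid_p(fill):
    """Probability grid (months, 9, 2, 3) from fill(month) scalars."""
    p = np.empty((N_MONTHS, 9, 2, 3))
    for m in range(1, N_MONTHS + 1):
        p[m - 1] = fill(m)
    return p.reshape(-1)


@pytest.fixture
def uniform_weights():
    w = np.full((9, 2, 3), 1.0 / 54)
    return make_weights(w)


class TestAggregateExcess:
    def test_identical_windows_give_exactly_zero(self, uniform_weights):
        p = np.tile(grid_p(lambda m: 0.002), (6, 1))
        est = aggregate_excess(make_draws(p), uniform_weights)
        assert np.all(est.draws == 0.0)
        assert est.mean == 0.0
        assert est.ci95 == (0.0, 0.0)

    def test_two_stratum_hand_oracle(self):
        """Two active strata with constant probabilities: the excess equals
        scalar arithmetic done by hand."""
        w = np.zeros((9, 2, 3))
        w[2, 0, 1] = 0.25
        w[6, 1, 2] = 0.75
        p = np.zeros((1, N_MONTHS, 9, 2, 3))
        p[:, :, 2, 0, 1] = 0.001          # baseline everywhere
        p[:, :, 6, 1, 2] = 0.004
        p[:, 13:, 2, 0, 1] = 0.0012       # pandemic months (14..22)
        p[:, 13:, 6, 1, 2] = 0.0044
        est = aggregate_excess(make_draws(p.reshape(1, -1)),
                               make_weights(w))
        pand = 0.25 * 0.0012 + 0.75 * 0.0044
        base = 0.25 * 0.001 + 0.75 * 0.004
        expect = 100.0 * (pand / base - 1.0)
        assert est.mean == pytest.approx(expect, abs=1e-12)

    def test_matches_brute_force_loop_exactly(self, rng, uniform_weights):
        """Vectorized aggregation equals an independent per-(draw, month,
        stratum) python loop."""
        p = rng.uniform(0.0005, 0.01, size=(5, 1188))
        draws = make_draws(p)
        est = aggregate_excess(draws, uniform_weights)
        w = _weight_array(uniform_weights)
        for d in range(5):
            agg = {}
            for window in [(14, 22), (2, 10)]:
                tot = 0.0
                for a in range(9):
                    for s in range(2):
                        for e in range(3):
                            vals = [p[d, cell_id(m, a, s, e)]
                                    for m in range(window[0],
                                                   window[1] + 1)]
                            tot += w[a, s, e] * float(np.mean(vals))
                agg[window] = tot
            expect = 100.0 * (agg[(14, 22)] / agg[(2, 10)] - 1.0)
            assert est.draws[d] == pytest.approx(expect, abs=1e-10)

    def test_missing_stratum_in_weights_is_an_error(self, uniform_weights):
        broken = uniform_weights.iloc[:-2]
        p = np.tile(grid_p(lambda m: 0.002), (2, 1))
        with pytest.raises(AggregationError, match="lacks strata"):
            aggregate_excess(make_draws(p), broken)

    def test_ci_nesting_and_mean_location(self, rng, uniform_weights):
        p = rng.uniform(0.0005, 0.01, size=(400, 1188))
        est = aggregate_excess(make_draws(p), uniform_weights)
        assert est.ci95[0] <= est.ci50[0] <= est.ci50[1] <= est.ci95[1]
        assert est.ci95[0] <= est.mean <= est.ci95[1]

    def test_uniform_log_odds_shift_is_recovered_exactly(
            self, uniform_weights):
        lam = 0.3
        base = grid_p(lambda m: 0.003).reshape(N_MONTHS, 9, 2, 3)
        shifted = base.copy()
        shifted[13:] = expit(logit(base[13:]) + lam)
        p = shifted.reshape(1, -1)
        out = aggregate_excess_log_odds(make_draws(p), uniform_weights)
        assert out[0] == pytest.approx(lam, abs=1e-12)


class TestAgeSpecific:
    def test_null_draws_give_zero_in_every_bin(self, uniform_weights):
        p = np.tile(grid_p(lambda m: 0.002), (4, 1))
        out = age_specific_excess(make_draws(p), uniform_weights,
                                  keep_draws=True)
        for label in AGE_BIN_LABELS:
            assert out[label].mean == 0.0

    def test_empty_age_bin_is_flagged_absent(self, uniform_weights):
        w = _weight_array(uniform_weights).copy()
        w[4] = 0.0
        w /= w.sum()
        p = np.tile(grid_p(lambda m: 0.002), (2, 1))
        out = age_specific_excess(make_draws(p), make_weights(w))
        assert out["40-49"] is None
        assert out["30-39"] is not None

    def test_single_active_bin_equals_overall(self, rng):
        w = np.zeros((9, 2, 3))
        w[5, 0, 0] = 0.6
        w[5, 1, 2] = 0.4
        weights = make_weights(w)
        p = rng.uniform(0.001, 0.01, size=(20, 1188))
        draws = make_draws(p)
        overall = aggregate_excess(draws, weights)
        by_age = age_specific_excess(draws, weights, keep_draws=True)
        np.testing.assert_allclose(by_age["50-59"].draws, overall.draws,
                                   rtol=1e-12)

    def test_share_weighted_rates_recover_overall(self, rng,
                                                  uniform_weights):
        """Age-bin rates combined with census age shares equal the overall
        rates draw by draw (linearity of the weighted sum)."""
        p = rng.uniform(0.001, 0.01, size=(10, 1188))
        draws = make_draws(p)
        overall = aggregate_excess(draws, uniform_weights)
        by_age = age_specific_excess(draws, uniform_weights,
                                     keep_draws=True)
        w = _weight_array(uniform_weights)
        shares = w.sum(axis=(1, 2))
        pand = sum(shares[a] * by_age[AGE_BIN_LABELS[a]].pandemic_rate_draws
                   for a in range(9))
        base = sum(shares[a] * by_age[AGE_BIN_LABELS[a]].baseline_rate_draws
                   for a in range(9))
        np.testing.assert_allclose(pand, overall.pandemic_rate_draws,
                                   rtol=1e-12)
        np.testing.assert_allclose(base, overall.baseline_rate_draws,
                                   rtol=1e-12)


class TestSensitivity:
    def test_null_draws_give_zero_rows(self, uniform_weights):
        p = np.tile(grid_p(lambda m: 0.002), (4, 1))
        fits = {o: make_draws(p, onset=o) for o in (14, 17, 20)}
        out = sensitivity_windows(fits, uniform_weights)
        assert list(out["onset_month"]) == [14, 17, 20]
        assert np.allclose(out["mean_percent"], 0.0)

    def test_single_onset_single_row(self, uniform_weights):
        p = np.tile(grid_p(lambda m: 0.002), (2, 1))
        out = sensitivity_windows({17: make_draws(p, onset=17)},
                                  uniform_weights)
        assert len(out) == 1
        assert out["window_start"].iloc[0] == 17

    def test_missing_onset_leaves_explicit_gap(self, uniform_weights):
        p = np.tile(grid_p(lambda m: 0.002), (2, 1))
        out = sensitivity_windows(
            {14: make_draws(p), 17: None}, uniform_weights)
        gap = out[out["onset_month"] == 17]
        assert bool(gap["missing"].iloc[0])
        assert np.isnan(gap["mean_percent"].iloc[0])


class TestEconSummary:
    def _econ(self, n, flagged, round_=1, income=1000.0, current=None):
        return pd.DataFrame({
            "household_id": np.arange(n),
            "round": round_,
            "earner_type": ["salaried"] * (n // 2)
                           + ["self_employed"] * (n - n // 2),
            "income_normal": income,
            "income_current": current if current is not None else income,
            "food_unavailable": [i < flagged for i in range(n)],
        })

    def test_printed_food_unavailability_proportions(self):
        econ = pd.concat([self._econ(2768, 683, round_=1),
                          self._econ(3289, 292, round_=2)])
        out = economic_summary(econ)
        food = out.food.set_index("round")
        assert food.loc[1, "percent_whole"] == 25
        assert food.loc[2, "percent_1dp"] == 8.9
        assert food.loc[1, "count"] == 683
        assert food.loc[1, "denominator"] == 2768

    def test_unchanged_income_gives_zero_percent_change(self):
        out = economic_summary(self._econ(100, 0))
        assert np.allclose(out.income["percent_change_may"], 0.0)

    def test_zero_normal_income_excluded_and_counted(self):
        econ = self._econ(10, 0)
        econ.loc[0, "income_normal"] = 0.0
        out = economic_summary(econ)
        assert out.excluded_zero_normal == 1

    def test_income_drop_ratio_of_means(self):
        econ = self._econ(4, 0, current=600.0)
        out = economic_summary(econ)
        assert np.allclose(out.income["percent_change_may"], -40.0)
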