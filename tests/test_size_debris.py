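import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import beta as beta_dist, f_oneway

import slicksurvey as ss
from slicksurvey.size_debris import (
    confound_screen, paired_log_response_ratios, squeeze_proportions,
)


def _length_survey(length_rows, debris_rows=None):
    """Build a minimal survey from (tow, habitat, length, count) rows."""
    tows = sorted({(t, h) for t, h, _, _ in length_rows})
    tow_df = pd.DataFrame({
        "tow_id": [t for t, _ in tows],
        "habitat": [h for _, h in tows],
        "site": "A",
        "minutes_from_solar_noon": 0,
        "volume_filtered_m3": 1.0,
    })
    counts = pd.DataFrame(
        [(t, "fish", "larva", c, float(L)) for t, _, L, c in length_rows],
        columns=["tow_id", "taxon_id", "life_stage", "count", "total_length_mm"],
    )
    taxa = pd.DataFrame({
        "taxon_id": ["fish"], "family": ["F"], "natal_habitat": ["other"],
        "functional_group": ["fish"],
    })
    debris = pd.DataFrame(
        debris_rows or [], columns=["tow_id", "category", "dry_weight_mg"]
    )
    return ss.Survey(tow_df, counts, taxa, debris)


class TestSizeHistogram:
    def test_counts_conserved_and_binned(self):
        survey = _length_survey([
            ("t1", "slick", 2, 2), ("t1", "slick", 3, 1), ("t2", "ambient", 2, 4),
        ])
        hist = ss.size_histogram(survey, bin_mm=1)
        assert hist["slick"].sum() == 3
        assert hist["ambient"].sum() == 4
        assert hist.loc[2, "slick"] == 2 and hist.loc[3, "slick"] == 1

    def test_simulated_lengths_right_skewed(self, sim_survey):
        survey, _ = sim_survey
        hist = ss.size_histogram(survey, bin_mm=1)
        totals = hist.sum(axis=1)
        assert totals.idxmax() <= 5  # modal bin at small sizes


class TestOccurrenceProportions:
    def test_equal_densities_half(self):
        survey = _length_survey([
            ("t1", "slick", 3, 5), ("t2", "ambient", 3, 5),
        ])
        tab = ss.occurrence_proportions(survey, bin_mm=5, nboot=200, seed=0)
        assert tab["p"].iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_zero_ambient_bin_squeezed_below_one(self):
        survey = _length_survey([
            ("t1", "slick", 3, 5), ("t2", "ambient", 3, 5),
            ("t1", "slick", 8, 4),   # no ambient fish in [5,10)
        ])
        tab = ss.occurrence_proportions(survey, bin_mm=5, nboot=200, seed=0)
        big = tab[tab["bin_low_mm"] == 5].iloc[0]
        assert big["p"] == 1.0
        assert 0.5 < big["p_squeezed"] < 1.0

    def test_invariant_to_common_density_rescaling(self, sim_survey):
        survey, _ = sim_survey
        tab1 = ss.occurrence_proportions(survey, bin_mm=5, nboot=400, seed=9)
        scaled = ss.Survey(
            survey.tows.assign(
                volume_filtered_m3=survey.tows["volume_filtered_m3"] * 3.0
            ),
            survey.counts, survey.taxa, survey.debris,
        )
        tab2 = ss.occurrence_proportions(scaled, bin_mm=5, nboot=400, seed=9)
        np.testing.assert_allclose(tab1["p"], tab2["p"], atol=1e-12)

    def test_generator_recovery_per_bin(self, sim_survey):
        """Empirical slick share per size bin tracks the generating
        logit-linear occurrence curve."""
        survey, truth = sim_survey
        tab = ss.occurrence_proportions(survey, bin_mm=5, nboot=1000, seed=1)
        eff = truth["size"]["effective_intercept"]
        slope = truth["size"]["logit_slope"]
        well_filled = tab[tab["n_fish"] >= 500]
        p_true = expit(eff + slope * well_filled["bin_mid_mm"])
        assert np.max(np.abs(well_filled["p"] - p_true)) < 0.03


class TestBetaRegression:
    def test_flat_proportions_give_zero_slope(self, rng):
        p = np.clip(0.5 + rng.normal(0, 0.01, 10), 0.01, 0.99)
        tab = pd.DataFrame({"bin_mid_mm": np.arange(10.0), "p_squeezed": p})
        fit = ss.beta_regression(tab)
        assert abs(fit.slope) < 0.02
        curve = fit.predict([0, 20, 40])
        assert np.ptp(curve) < 0.1

    def test_boundary_rejected(self):
        tab = pd.DataFrame({
            "bin_mid_mm": [1.0, 2.0, 3.0, 4.0],
            "p_squeezed": [0.2, 0.4, 0.6, 1.0],
        })
        with pytest.raises(ValueError, match="squeeze"):
            ss.beta_regression(tab)

    def test_loglikelihood_maximal_at_fit(self, rng):
        L = np.arange(3.0, 18.1, 2.0)
        true = expit(-2 + 0.3 * L)
        obs = beta_dist(true * 50, (1 - true) * 50).rvs(random_state=42)
        tab = pd.DataFrame({"bin_mid_mm": L, "p_squeezed": obs})
        fit = ss.beta_regression(tab)

        def loglik(intercept, slope, phi):
            mu = expit(intercept + slope * L)
            return beta_dist(mu * phi, (1 - mu) * phi).logpdf(obs).sum()

        best = loglik(fit.intercept, fit.slope, fit.precision)
        for factor in (0.9, 1.1):
            assert best >= loglik(fit.intercept * factor, fit.slope, fit.precision) - 1e-6
            assert best >= loglik(fit.intercept, fit.slope * factor, fit.precision) - 1e-6
            assert best >= loglik(fit.intercept, fit.slope, fit.precision * factor) - 1e-6

    def test_monotone_fit_iff_positive_slope(self, rng):
        L = np.arange(3.0, 18.1, 2.0)
        true = expit(-2 + 0.3 * L)
        obs = beta_dist(true * 50, (1 - true) * 50).rvs(random_state=7)
        fit = ss.beta_regression(pd.DataFrame({"bin_mid_mm": L, "p_squeezed": obs}))
        grid = fit.predict(np.linspace(0, 40, 50))
        assert fit.slope > 0
        assert (np.diff(grid) > 0).all()


class TestSqueeze:
    def test_boundary_moved_inside(self):
        p = squeeze_proportions(np.array([0.0, 0.5, 1.0]), n=10)
        assert 0 < p[0] < p[1] < p[2] < 1


class TestDebrisDensityRegression:
    def test_perfect_loglog_relation_r2_one(self):
        # counts = debris^2 at volume 1 -> log density = 2 log debris exactly
        debris_values = [1, 2, 3, 4, 5, 6]
        rows, debris = [], []
        for i, d in enumerate(debris_values):
            tid = f"s{i}"
            rows.append((tid, "slick", 3, d * d))
            debris.append((tid, "organic", d))
        for i in range(3):   # ambient stratum just to satisfy the survey shape
            rows.append((f"a{i}", "ambient", 3, 2 + i))
            debris.append((f"a{i}", "organic", 1 + i))
        survey = _length_survey(rows, debris)
        table = ss.debris_density_regression(survey)
        slick = table[(table["habitat"] == "slick") & (table["size_class"] == "<5")]
        assert slick["r2"].iloc[0] == pytest.approx(1.0)
        assert slick["slope"].iloc[0] == pytest.approx(2.0)

    def test_coupling_strength_orders_r2(self, rng):
        """Stronger debris-density coupling in larger size classes shows up
        as increasing R^2 across classes."""
        mids = {"<5": 3, "5-10": 7, "10-15": 12, "15-20": 17, ">20": 25}
        noise_sd = {"<5": 1.2, "5-10": 0.8, "10-15": 0.5, "15-20": 0.3, ">20": 0.1}
        rows, debris = [], []
        for i in range(40):
            tid = f"s{i}"
            d = float(rng.lognormal(1.0, 0.8))
            debris.append((tid, "organic", d))
            for label, mid in mids.items():
                dens = np.exp(1.0 * np.log(d) + rng.normal(0, noise_sd[label]))
                rows.append((tid, "slick", mid, max(int(round(dens * 10)), 1)))
        for i in range(5):
            rows.append((f"a{i}", "ambient", 3, 1))
            debris.append((f"a{i}", "organic", 1.0))
        survey = _length_survey(rows, debris)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = ss.debris_density_regression(survey)
        slick = table[table["habitat"] == "slick"].set_index("size_class")
        r2 = slick.loc[["<5", "5-10", "10-15", "15-20", ">20"], "r2"]
        assert r2.iloc[-1] > r2.iloc[0]
        assert r2.is_monotonic_increasing


class TestConfoundScreen:
    def test_f_equals_t_squared_on_two_groups(self, rng):
        x = rng.normal(0, 1, 12)
        pair_table = pd.DataFrame({
            "log_ratio": x,
            "gear": ["ring"] * 6 + ["ik"] * 6,
        })
        table = confound_screen(pair_table, factors=("gear",))
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(x[:6], x[6:])
        assert table["F"].iloc[0] == pytest.approx(t**2, rel=1e-10)

    def test_matches_f_oneway(self, rng):
        groups = np.repeat(["a", "b", "c"], 10)
        y = rng.normal(0, 1, 30) + (groups == "b") * 0.5
        table = confound_screen(
            pd.DataFrame({"log_ratio": y, "year": groups}), factors=("year",)
        )
        F, p = f_oneway(y[groups == "a"], y[groups == "b"], y[groups == "c"])
        assert table["F"].iloc[0] == pytest.approx(F, rel=1e-10)
        assert table["p"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_null_factors_not_significant_on_average(self, rng):
        """Factors independent of the ratios give F near 1 on average."""
        fs = []
        for _ in range(100):
            pair_table = pd.DataFrame({
                "log_ratio": rng.normal(0, 1, 24),
                "year": rng.choice(["2016", "2017", "2018"], 24),
            })
            t = confound_screen(pair_table, factors=("year",))
            if len(t):
                fs.append(t["F"].iloc[0])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_single_level_factor_skipped(self):
        pair_table = pd.DataFrame({
            "log_ratio": [0.1, 0.2, 0.3], "gear": ["ring"] * 3,
        })
        with pytest.warns(UserWarning, match="single level"):
            table = confound_screen(pair_table, factors=("gear",))
        assert len(table) == 0

    def test_paired_ratios_from_simulated_survey(self, sim_survey):
        survey, _ = sim_survey
        pairs = paired_log_response_ratios(survey)
        assert len(pairs) == 52
        screen = confound_screen(pairs)
        assert {"year", "gear", "sampling_order"} <= set(screen["factor"])
        # design factors are independent of enrichment in the generator
        assert (screen["p"] > 0.001).all()


class TestAncova:
    def test_habitat_effect_detected(self, sim_survey):
        survey, _ = sim_survey
        table = ss.ancova(survey, subset="all")
        table = table.set_index("term")
        assert "C(habitat)" in table.index
        # simulated slicks are strongly enriched: huge habitat F
        assert table.loc["C(habitat)", "F"] > 10
        for sub in ("small", "large"):
            t = ss.ancova(survey, subset=sub).set_index("term")
            assert np.isfinite(t.loc["C(habitat)", "F"])
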