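"""Logistic enrichment model and matched-resampling simulation test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from cpgvar.enrichment import (
    StratumScheme,
    assign_strata,
    bin_by_reported_p,
    category_enrichment,
    feasible_index,
    fit_enrichment_model,
    matched_simulation_test,
)
from cpgvar.errors import (
    CollinearityError,
    ConfigError,
    InfeasibleMatchingError,
    SchemaError,
    SeparationError,
)
from cpgvar.synth import SynthConfig, generate_proxy_covariates, plant_outcomes


def model_data(n, seed, beta_cgsnpt, beta0=-3.0, beta_maf=0.5, beta_tags=0.02):
    """Outcome data drawn from the logistic enrichment model itself."""
    proxies = generate_proxy_covariates(n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    eta = (
        beta0
        + beta_cgsnpt * proxies["is_cgsnpt"].to_numpy()
        + beta_maf * proxies["maf"].to_numpy()
        + beta_tags * proxies["n_tagged"].to_numpy()
    )
    return pd.DataFrame(
        {
            "y": (rng.random(n) < expit(eta)).astype(int),
            "x_cgsnpt": proxies["is_cgsnpt"].astype(int),
            "x_maf": proxies["maf"],
            "x_tags": proxies["n_tagged"],
        }
    )


class TestFitEnrichmentModel:
    def test_recovers_planted_odds_ratio(self):
        data = model_data(50_000, seed=5, beta_cgsnpt=math.log(1.5))
        result = fit_enrichment_model(data)
        assert result.converged
        assert result.ci_low <= 1.5 <= result.ci_high
        assert result.or_cgsnpt == pytest.approx(1.5, rel=0.15)

    def test_matches_generic_optimizer_on_small_instance(self):
        """MLE agrees to 4 decimals with a scipy minimization of the
        hand-written log-likelihood (the independent route)."""
        data = model_data(200, seed=9, beta_cgsnpt=0.8, beta0=-0.5)
        result = fit_enrichment_model(data)
        X = np.column_stack(
            [np.ones(len(data)), data["x_cgsnpt"], data["x_maf"], data["x_tags"]]
        )
        y = data["y"].to_numpy()

        def negloglik(beta):
            eta = X @ beta
            return -(y * eta - np.logaddexp(0.0, eta)).sum()

        opt = minimize(negloglik, np.zeros(4), method="BFGS", tol=1e-10)
        fitted = np.array(
            [result.beta0, result.beta_cgsnpt, result.beta_maf, result.beta_tags]
        )
        assert np.allclose(fitted, opt.x, atol=1e-4)

    def test_single_outcome_state_rejected(self):
        data = model_data(100, seed=3, beta_cgsnpt=0.0)
        data["y"] = 0
        with pytest.raises(CollinearityError):
            fit_enrichment_model(data)

    def test_constant_cgsnpt_rejected(self):
        data = model_data(100, seed=3, beta_cgsnpt=0.0)
        data["x_cgsnpt"] = 1
        with pytest.raises(CollinearityError):
            fit_enrichment_model(data)

    def test_perfect_separation_raises(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "x_cgsnpt": [0, 0, 0, 1, 1, 1] * 5,
                "x_maf": rng.random(30) * 0.5,
                "x_tags": rng.integers(0, 4, size=30),
            }
        )
        data["y"] = data["x_cgsnpt"]
        with pytest.raises(SeparationError):
            fit_enrichment_model(data)


class TestAssignStrata:
    def test_maf_and_tag_bin_examples(self):
        scheme = StratumScheme()
        proxies = pd.DataFrame(
            {"maf": [0.12, 0.12, 0.02], "n_tagged": [0, 0, 12]}
        )
        codes = assign_strata(proxies, scheme)
        assert codes.iloc[0] == codes.iloc[1]  # identical snps, identical label
        # maf 0.12 -> third maf bin [0.10, 0.15); tag 0 -> first tag bin
        assert codes.iloc[0] == 2 * scheme.n_tag_bins
        # maf 0.02 -> first maf bin; 12 tags -> last tag bin
        assert codes.iloc[2] == scheme.n_tag_bins - 1

    def test_upper_maf_edge_is_covered(self):
        codes = assign_strata(pd.DataFrame({"maf": [0.5], "n_tagged": [1]}))
        assert codes.iloc[0] == 9 * StratumScheme().n_tag_bins + 1

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ConfigError):
            assign_strata(pd.DataFrame({"maf": [0.6], "n_tagged": [0]}))


@pytest.fixture(scope="module")
def panel():
    proxies = generate_proxy_covariates(8000, seed=21)
    strata = assign_strata(proxies, StratumScheme())
    return proxies, strata


class TestMatchedSimulationTest:

    def test_every_draw_reproduces_index_stratum_composition(self, panel):
        proxies, strata = panel
        rng = np.random.default_rng(2)
        index_ids = proxies["snp_id"].sample(300, random_state=7).tolist()
        result = matched_simulation_test(
            index_ids, proxies, strata, n_draws=50, seed=4, return_draws=True
        )
        codes = strata.to_numpy()
        id_to_pos = {s: i for i, s in enumerate(proxies["snp_id"])}
        index_pos = np.array([id_to_pos[s] for s in index_ids])
        expected = pd.Series(codes[index_pos]).value_counts().sort_index()
        for draw in result.draws:
            assert len(draw) == len(index_ids)
            assert len(np.unique(draw)) == len(draw)  # without replacement
            assert not np.isin(draw, index_pos).any()  # index excluded from pool
            got = pd.Series(codes[draw]).value_counts().sort_index()
            pd.testing.assert_series_equal(got, expected)

    def test_zero_observed_gives_p_of_one(self, panel):
        proxies, strata = panel
        non_cg = proxies.loc[~proxies["is_cgsnpt"], "snp_id"].head(100).tolist()
        result = matched_simulation_test(non_cg, proxies, strata, n_draws=40, seed=1)
        assert result.observed_count == 0
        assert result.empirical_p == 1.0

    def test_same_seed_reproduces_null_counts(self, panel):
        proxies, strata = panel
        index_ids = proxies["snp_id"].head(200).tolist()
        a = matched_simulation_test(index_ids, proxies, strata, n_draws=60, seed=5)
        b = matched_simulation_test(index_ids, proxies, strata, n_draws=60, seed=5)
        assert np.array_equal(a.null_counts, b.null_counts)

    def test_p_label_reports_resolution_when_no_draw_reaches_observed(self, panel):
        proxies, strata = panel
        cg = proxies.loc[proxies["is_cgsnpt"], "snp_id"].head(400).tolist()
        result = matched_simulation_test(cg, proxies, strata, n_draws=50, seed=6)
        if result.empirical_p == 0.0:
            assert result.p_label.startswith("<")

    def test_plus_one_estimator_never_zero(self, panel):
        proxies, strata = panel
        cg = proxies.loc[proxies["is_cgsnpt"], "snp_id"].head(400).tolist()
        result = matched_simulation_test(
            cg, proxies, strata, n_draws=50, seed=6, plus_one=True
        )
        assert result.empirical_p >= 1 / 51

    def test_infeasible_stratum_is_named(self):
        proxies = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "maf": [0.1, 0.1, 0.4],
                "n_tagged": [0, 0, 0],
                "is_cgsnpt": [True, False, True],
            }
        )
        strata = assign_strata(proxies)
        with pytest.raises(InfeasibleMatchingError):
            matched_simulation_test(["a", "b"], proxies, strata, n_draws=5, seed=0)

    def test_feasible_index_respects_stratum_capacity(self, panel):
        """Index sets built with feasible_index always leave each stratum a
        sampling pool at least as large as its index count."""
        proxies, strata = panel
        candidates = proxies["snp_id"].tolist()
        index_ids = feasible_index(candidates, proxies, strata, 2000)
        codes = strata.to_numpy()
        pos_of = {s: i for i, s in enumerate(proxies["snp_id"])}
        taken = pd.Series(codes[[pos_of[s] for s in index_ids]]).value_counts()
        sizes = pd.Series(codes).value_counts()
        for code, count in taken.items():
            assert count <= sizes[code] - count
        # and the matched test therefore runs without infeasibility
        matched_simulation_test(index_ids, proxies, strata, n_draws=5, seed=0)

    def test_empirical_p_nonincreasing_in_observed_count(self, panel):
        proxies, strata = panel
        index_ids = proxies["snp_id"].head(200).tolist()
        result = matched_simulation_test(index_ids, proxies, strata, n_draws=80, seed=9)
        null = result.null_counts
        ps = [(null >= k).mean() for k in range(0, len(index_ids) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBinByReportedP:
    def test_bin_assignment_examples(self):
        frame = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "reported_p": [3e-6, 1e-20, 2e-4]}
        )
        out = bin_by_reported_p(frame)
        binned = dict(zip(out["snp_id"], out["p_bin"]))
        assert binned["a"] == "E-5~"
        assert binned["b"] == "E-20~"
        assert "c" not in binned  # above the 1e-5 catalog filter

    def test_invalid_p_rejected(self):
        with pytest.raises(SchemaError):
            bin_by_reported_p(pd.DataFrame({"snp_id": ["a"], "reported_p": [0.0]}))

    def test_nonincreasing_edges_rejected(self):
        with pytest.raises(ConfigError):
            bin_by_reported_p(
                pd.DataFrame({"snp_id": ["a"], "reported_p": [1e-9]}),
                edges_neglog10=[5, 5, 7],
            )


class TestCategoryEnrichment:
    def test_recovers_planted_category_contrast(self):
        config = SynthConfig(
            seed=31, trait_categories={"cancer": 1.8, "other": 1.0}, beta0=-2.5
        )
        proxies = generate_proxy_covariates(40_000, seed=31)
        outcomes, _ = plant_outcomes(proxies, config, kind="trait")
        results = category_enrichment(outcomes, proxies)
        assert results["cancer"].or_cgsnpt > results["other"].or_cgsnpt

    def test_single_category_matches_pooled(self):
        config = SynthConfig(seed=13, trait_categories={"only": 1.4})
        proxies = generate_proxy_covariates(5000, seed=13)
        outcomes, _ = plant_outcomes(proxies, config, kind="trait")
        results = category_enrichment(outcomes, proxies)
        assert results["only"].or_cgsnpt == pytest.approx(
            results["pooled"].or_cgsnpt
        )
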