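"""NB GLM fitting, dispersion estimation, quasi-likelihood F-tests, BH, and
the full contrast runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special

from atacdiff.differential import (
    LEVEL_PRESETS,
    DesignSpec,
    NBQLFTester,
    bh_adjust,
    estimate_dispersions,
    fit_nb_glm,
    fit_nb_glm_batched,
    nb_deviance,
    ql_f_test,
    run_contrast,
    squeeze_var,
)
from atacdiff.simulate import SimulationConfig, simulate_dataset
from conftest import two_group_design

TWO_GROUP = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
INTERCEPT = np.ones((12, 1))


def nb_nll(beta, y, X, offset, phi):
    mu = np.exp(X @ beta + offset)
    r = 1.0 / phi
    return -np.sum(
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    )


class TestGlmFit:
    def test_poisson_limit_matches_group_mean_ratio(self, rng):
        y = rng.poisson([5.0] * 6 + [40.0] * 6).astype(float)
        beta, dev, mu = fit_nb_glm(y, TWO_GROUP, np.zeros(12), 1e-12)
        expected = np.log(y[6:].mean() / y[:6].mean())
        assert beta[1] == pytest.approx(expected, abs=1e-6)

    def test_saturated_design_zero_deviance(self, rng):
        y = rng.poisson(20.0, size=4).astype(float) + 1
        X = np.eye(4)
        beta, dev, mu = fit_nb_glm(y, X, np.zeros(4), 0.1)
        assert dev == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(mu, y, atol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_deviance_matches_direct_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        phi = 0.3
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * 30.0), size=12).astype(float) + 1
        offset = rng.normal(0, 0.2, 12)
        _, dev, _ = fit_nb_glm(y, TWO_GROUP, offset, phi)
        best = np.inf
        for x0 in ([1.0, 0.0], [3.0, 0.5], [2.0, -0.5]):
            res = optimize.minimize(
                nb_nll, x0, args=(y, TWO_GROUP, offset, phi), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            best = min(best, res.fun)
        # deviance = 2 * (ll_saturated - ll_at_optimum)
        mu_sat = y
        r = 1 / phi
        ll_sat = np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu_sat)) + y * np.log(mu_sat / (r + mu_sat))
        )
        dev_oracle = 2 * (ll_sat + best)
        assert dev == pytest.approx(dev_oracle, abs=1e-4)

    def test_batched_agrees_with_single_row(self, rng):
        Y = rng.poisson(30.0, size=(20, 12)).astype(float)
        phi = np.full(20, 0.15)
        fit = fit_nb_glm_batched(Y, TWO_GROUP, np.zeros(12), phi)
        for g in (0, 7, 19):
            beta, dev, _ = fit_nb_glm(Y[g], TWO_GROUP, np.zeros(12), 0.15)
            assert np.allclose(fit.beta[g], beta, atol=1e-6)
            assert fit.deviance[g] == pytest.approx(dev, abs=1e-6)


class TestDispersions:
    def _simulate(self, seed, phi, G=400, n=40):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(20, 200, G)[:, None] * np.ones(n)
        if phi > 0:
            lam = rng.gamma(1 / phi, phi * mu)
        else:
            lam = mu
        return rng.poisson(lam).astype(float)

    def test_common_dispersion_recovery(self):
        X = np.column_stack([np.ones(40), np.repeat([0, 1.0], 20)])
        estimates = [
            estimate_dispersions(self._simulate(s, 0.1), X, np.zeros(40)).common
            for s in range(5)
        ]
        assert all(0.07 <= e <= 0.13 for e in estimates)

    def test_poisson_boundary(self):
        X = np.column_stack([np.ones(40), np.repeat([0, 1.0], 20)])
        est = estimate_dispersions(self._simulate(0, 0.0), X, np.zeros(40))
        assert est.common <= 0.01

    def test_infinite_prior_df_gives_trend_exactly(self):
        X = np.column_stack([np.ones(40), np.repeat([0, 1.0], 20)])
        Y = self._simulate(1, 0.2)
        est = estimate_dispersions(Y, X, np.zeros(40), prior_df=np.inf)
        assert np.array_equal(est.tagwise, est.trended)

    def test_all_zero_rows_excluded_with_warning(self):
        X = np.column_stack([np.ones(40), np.repeat([0, 1.0], 20)])
        Y = self._simulate(2, 0.1)
        Y[5] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            est = estimate_dispersions(Y, X, np.zeros(40))
        assert est.excluded_all_zero == [5]
        assert est.tagwise[5] == pytest.approx(est.common)


class TestQlfTest:
    def test_identical_designs_rejected(self, rng):
        Y = rng.poisson(20.0, size=(10, 12)).astype(float)
        with pytest.raises(ValueError, match="empty"):
            ql_f_test(Y, TWO_GROUP, TWO_GROUP, np.zeros(12), np.full(10, 0.1))

    def test_planted_effects_detected(self):
        rng = np.random.default_rng(42)
        G, n, phi, k = 1000, 40, 0.2, 50
        group = np.repeat([0.0, 1.0], 20)
        X = np.column_stack([np.ones(n), group])
        base = rng.uniform(20, 200, G)
        lfc = np.zeros(G)
        lfc[:k] = 2.0
        mu = base[:, None] * 2.0 ** (lfc[:, None] * group[None, :])
        Y = rng.poisson(rng.gamma(1 / phi, phi * mu))
        disp = estimate_dispersions(Y, X, np.zeros(n))
        res = ql_f_test(Y, X, np.ones((n, 1)), np.zeros(n), disp.trended)
        q = bh_adjust(res["p"])
        assert (q[:k] < 0.05).mean() >= 0.8
        false = (q[k:] < 0.05).sum()
        assert false / max((q < 0.05).sum(), 1) <= 0.1

    def test_squeeze_var_moment_fit(self, rng):
        df = 10
        s2 = rng.chisquare(df, size=2000) / df
        d0, v0, post = squeeze_var(s2, df)
        assert v0 == pytest.approx(1.0, abs=0.05)
        assert post.shape == s2.shape
        # moderation pulls extremes toward the prior
        assert post.max() < s2.max() and post.min() > s2.min()


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_step_function_of_ranked_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=80))
    def test_bh_properties(self, ps):
        """q >= p elementwise, q <= 1, and q is monotone in ranked p."""
        p = np.asarray(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(
        n_peaks=600, seed=19, design=two_group_design(8),
        frac_cell_type=0.0, frac_disease=0.05, latent_effect_sd=0.0,
    )
    peaks, meta, counts, regions, truth = simulate_dataset(cfg)
    return counts, meta


class TestRunContrast:
    SPEC = DesignSpec("t", "disease", "non_neuronal", "all", paired_donors_only=False)

    def test_no_sex_chromosome_rows(self, dataset):
        counts, meta = dataset
        res = run_contrast(counts, meta, self.SPEC)
        assert not res["chrom"].str.lower().str.contains("chrx|chry").any()
        assert set(res["direction"]) <= {
            "more_accessible_in_case", "less_accessible_in_case"
        }

    def test_group_size_guard(self, dataset):
        counts, meta = dataset
        tiny = meta.iloc[:3]
        with pytest.raises(ValueError, match=">=2 samples"):
            run_contrast(counts[tiny.index], tiny, self.SPEC)

    def test_ordering_invariance(self, dataset, rng):
        counts, meta = dataset
        res = run_contrast(counts, meta, self.SPEC)
        perm_counts = counts.iloc[rng.permutation(len(counts)),
                                  rng.permutation(counts.shape[1])]
        res_perm = run_contrast(perm_counts, meta, self.SPEC)
        a = res.set_index("peak_id").sort_index()
        b = res_perm.set_index("peak_id").sort_index()
        assert np.allclose(a["p"], b["p"], atol=1e-8)
        assert np.allclose(a["log2FC"], b["log2FC"], atol=1e-8)

    def test_label_swap_negates_logfc(self, dataset):
        counts, meta = dataset
        res = run_contrast(counts, meta, self.SPEC)
        flipped = meta.copy()
        flipped["is_case"] = ~flipped["is_case"].astype(bool)
        res_f = run_contrast(counts, flipped, self.SPEC)
        assert np.allclose(res["log2FC"], -res_f["log2FC"], atol=1e-6)
        assert np.allclose(res["p"], res_f["p"], atol=1e-8)

    def test_unknown_covariate_rejected(self, dataset):
        counts, meta = dataset
        with pytest.raises(ValueError, match="covariates"):
            run_contrast(counts, meta, self.SPEC, covariates=["nope"])


def test_level_preset_cohort_arithmetic():
    l2 = LEVEL_PRESETS["L2_non_neuronal"].nominal_n
    assert LEVEL_PRESETS["L3A"].nominal_n[0] + LEVEL_PRESETS["L3B"].nominal_n[0] == l2[0]
    assert LEVEL_PRESETS["L3A"].nominal_n[1] + LEVEL_PRESETS["L3B"].nominal_n[1] == l2[1]
    assert LEVEL_PRESETS["L1"].nominal_n == (40, 40)
    assert LEVEL_PRESETS["L3E"].nominal_n == (14, 13)


def test_confounding_inflates_without_adjustment():
    # a technical covariate aligned with the case labels inflates discoveries
    # unless it is included in the design
    from atacdiff.simulate import simulate_counts, simulate_metadata, simulate_peak_universe

    cfg = SimulationConfig(
        n_peaks=800, seed=77, design=two_group_design(10),
        frac_cell_type=0.0, frac_disease=0.0,
        confounders=(("batch_metric", 1.0, "continuous", 1),),
        latent_effect_sd=0.6,
    )
    peaks = simulate_peak_universe(cfg)
    meta = simulate_metadata(cfg)
    # align the latent factor with case status to create confounding
    latent = np.where(meta["is_case"], 1.2, -1.2) + 0.1 * np.random.default_rng(1).standard_normal(len(meta))
    meta.attrs["latent"] = pd.Series(latent, index=meta.index)
    meta["batch_metric"] = latent
    counts, _ = simulate_counts(cfg, peaks, meta)
    spec = DesignSpec("t", "disease", "non_neuronal", "all", paired_donors_only=False)
    unadj = run_contrast(counts, meta, spec)
    adj = run_contrast(counts, meta, spec, covariates=["batch_metric"])
    assert int(unadj["significant"].sum()) > 20
    assert int(adj["significant"].sum()) <= 2


def test_nbqlf_tester_estimator(rng):
    X = pd.DataFrame(
        rng.poisson(50, size=(16, 300)), index=[f"s{i}" for i in range(16)]
    )
    y = np.repeat([False, True], 8)
    tester = NBQLFTester().fit(X, y)
    assert len(tester.results_) <= 300
    assert {"log2FC", "p", "q", "direction"} <= set(tester.results_.columns)
    assert int(tester.results_["significant"].sum()) == 0
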