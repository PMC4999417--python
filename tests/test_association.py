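import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from finemapkit.association import (
    cochran_armitage_trend,
    conditional_scan,
    filter_variants,
    impute_info_score,
    logistic_fit,
    trend_test_dosage,
)
from finemapkit.genotypes import GenotypeTable
from finemapkit.synthetic_data import add_genotype_uncertainty


def _expand(counts):
    """2x3 table -> individual (dose, status) observations."""
    g = np.concatenate(
        [np.repeat([0, 1, 2], counts[0]), np.repeat([0, 1, 2], counts[1])]
    )
    y = np.repeat([1, 0], [sum(counts[0]), sum(counts[1])])
    return g, y


tables = st.lists(st.integers(0, 60), min_size=6, max_size=6).filter(
    lambda c: sum(c[:3]) > 0 and sum(c[3:]) > 0
)


class TestTrendTest:
    def test_identical_distributions_give_zero(self):
        res = cochran_armitage_trend([[25, 50, 25], [25, 50, 25]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    @given(tables)
    def test_matches_n_times_squared_correlation(self, c):
        """Armitage's statistic equals N * corr(dose, status)^2."""
        counts = [c[:3], c[3:]]
        g, y = _expand(counts)
        res = cochran_armitage_trend(counts)
        if np.ptp(g) == 0:
            assert res.degenerate
            return
        oracle = len(g) * np.corrcoef(g, y)[0, 1] ** 2
        assert res.chi2 == pytest.approx(oracle, abs=1e-9)

    def test_textbook_example_against_direct_summation(self):
        counts = np.array([[10, 40, 50], [50, 40, 10]], dtype=float)
        w = np.array([0, 1, 2])
        N, R = counts.sum(), counts[0].sum()
        n_j, r_j = counts.sum(axis=0), counts[0]
        num = sum(w[j] * (r_j[j] * N - R * n_j[j]) for j in range(3))
        var = R * (N - R) * (N * sum(w[j] ** 2 * n_j[j] for j in range(3)) - sum(w[j] * n_j[j] for j in range(3)) ** 2)
        assert cochran_armitage_trend(counts).chi2 == pytest.approx(N * num**2 / var, abs=1e-9)

    @given(tables)
    def test_case_control_swap_invariance(self, c):
        counts = [c[:3], c[3:]]
        a = cochran_armitage_trend(counts)
        b = cochran_armitage_trend(counts[::-1])
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-9)
        assert a.chi2 >= 0

    def test_monomorphic_is_degenerate(self):
        res = cochran_armitage_trend([[30, 0, 0], [40, 0, 0]])
        assert res == (0.0, 1.0, True)

    @given(tables)
    def test_equals_logistic_score_statistic(self, c):
        """Trend chi-square is the score test of the additive logistic model."""
        import statsmodels.api as sm

        counts = [c[:3], c[3:]]
        g, y = _expand(counts)
        if np.ptp(g) == 0 or np.ptp(y) == 0:
            return
        model = sm.Logit(y, sm.add_constant(g.astype(float)))
        null = np.array([logit(y.mean()), 0.0])
        score = model.score(null)
        info = -model.hessian(null)
        stat = float(score @ np.linalg.solve(info, score))
        res = cochran_armitage_trend(counts)
        assert res.chi2 == pytest.approx(stat, rel=1e-6, abs=1e-9)

    def test_dosage_form_agrees_on_hard_calls(self):
        counts = [[10, 40, 50], [50, 40, 10]]
        g, y = _expand(counts)
        assert trend_test_dosage(g, y).chi2 == pytest.approx(
            cochran_armitage_trend(counts).chi2, abs=1e-9
        )


class TestLogisticFit:
    def test_balanced_independence_gives_zero_beta(self):
        g = np.array([0.0, 1.0, 0.0, 1.0] * 10)
        y = np.array([0.0, 0.0, 1.0, 1.0] * 10)
        fit = logistic_fit(g, y)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_recovers_case_fraction(self):
        y = np.array([1] * 7 + [0] * 13, dtype=float)
        fit = logistic_fit(None, y)
        assert expit(fit.beta[0]) == pytest.approx(7 / 20, abs=1e-9)

    def test_matches_grid_search_maximizer(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=20).astype(float)
        y = (rng.random(20) < expit(-0.5 + 0.6 * g)).astype(float)

        def loglik(b0, b1):
            p = expit(b0 + b1 * g)
            return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        b0, b1, span = 0.0, 0.0, 3.0
        for _ in range(6):  # coarse-to-fine refinement
            grid0 = np.linspace(b0 - span, b0 + span, 41)
            grid1 = np.linspace(b1 - span, b1 + span, 41)
            ll = np.array([[loglik(a, b) for b in grid1] for a in grid0])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            b0, b1, span = grid0[i], grid1[j], span / 10
        fit = logistic_fit(g, y)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(b0, abs=1e-4)
        assert fit.beta[1] == pytest.approx(b1, abs=1e-4)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, 300).astype(float)
        cov = rng.normal(size=300)
        y = (rng.random(300) < expit(-1 + 0.4 * g + 0.3 * cov)).astype(float)
        fit = logistic_fit(g, y, covariates=cov[:, None])
        ref = sm.Logit(y, np.column_stack([np.ones(300), g, cov])).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_separation_is_flagged(self):
        g = np.array([0.0] * 10 + [2.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = logistic_fit(g, y)
        assert not fit.converged


class TestInfoScore:
    def test_hard_calls_give_one(self):
        probs = np.zeros((50, 3))
        probs[:20, 0] = 1
        probs[20:40, 1] = 1
        probs[40:, 2] = 1
        assert impute_info_score(probs).info == pytest.approx(1.0)

    def test_hwe_prior_triples_give_zero(self):
        # f - e^2 = 1.5 - 1 = 0.5 = 2 theta(1-theta) at theta = 0.5
        probs = np.tile([0.25, 0.5, 0.25], (100, 1))
        res = impute_info_score(probs)
        assert res.info == pytest.approx(0.0, abs=1e-12)
        assert not res.degenerate

    def test_decreasing_in_added_uncertainty(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=1000)
        infos = [
            impute_info_score(add_genotype_uncertainty(g, c).reshape(-1, 3)).info
            for c in [1.0, 0.97, 0.93, 0.9, 0.85]
        ]
        assert infos[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(infos, infos[1:]))
        assert 0.0 < infos[-1] < 1.0

    def test_malformed_triples_rejected(self):
        with pytest.raises(ValueError):
            impute_info_score(np.array([[0.5, 0.2, 0.2]]))


def _toy_table(dosages, ids=None):
    n = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": ids or [f"v{j}" for j in range(n)],
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 100,
            "ref": "C",
            "alt": "A",
        }
    )
    return GenotypeTable(variants, dosages)


class TestFilterAndConditional:
    def test_maf_boundary_is_strict(self):
        res = pd.DataFrame(
            {
                "variant_id": ["a", "b"],
                "maf": [0.01, 0.011],
                "info": [1.0, 1.0],
                "p_trend": [1e-9, 1e-9],
            }
        )
        out = filter_variants(res)
        assert list(out["variant_id"]) == ["b"]

    def test_disabled_thresholds_are_identity(self):
        res = pd.DataFrame(
            {
                "variant_id": list("abc"),
                "maf": [0.4, 0.005, 0.2],
                "info": [1.0, 0.2, 0.5],
                "p_trend": [0.9, 0.5, 1e-8],
            }
        )
        out = filter_variants(res, maf_min=0.0, info_min=0.0, p_max=np.inf)
        assert list(out["variant_id"]) == list("abc")

    def test_copy_of_lead_flagged_collinear(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(200, 1)).astype(float)
        dosages = np.column_stack([g, g, rng.integers(0, 3, 200)])
        table = _toy_table(dosages, ids=["lead", "copy", "other"])
        y = rng.integers(0, 2, 200)
        out = conditional_scan(table, y, "lead")
        row = out.set_index("variant_id").loc["copy"]
        assert bool(row["collinear"])
        assert np.isnan(row["p"])
        assert not out.set_index("variant_id").loc["other", "collinear"]

    def test_wald_and_trend_p_agree_on_powered_data(self):
        from finemapkit.association import associate
        from finemapkit.synthetic_data import simulate_case_control, simulate_haplotypes

        haps = simulate_haplotypes([0.35], [1.0], 20_000, seed=42)
        table, y = simulate_case_control(haps, 0, 1.35, 1_920, 5_199, seed=43)
        res = associate(table, y).iloc[0]
        assert abs(np.log10(res["p_wald"]) - np.log10(res["p_trend"])) <= 1.0

    def test_monomorphic_lead_rejected(self):
        table = _toy_table(np.column_stack([np.ones(50), np.arange(50) % 3]))
        with pytest.raises(ValueError, match="monomorphic"):
            conditional_scan(table, np.arange(50) % 2, "v0")
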