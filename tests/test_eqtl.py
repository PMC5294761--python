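"""Expression preprocessing, cis windows, OLS eQTL fit, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from credset.eqtl import (
    CisEqtlModel,
    PowerSpec,
    cis_pairs,
    eqtl_power,
    filter_low_expression,
    fit_cis_eqtl,
    normalize_library_size,
    rank_inverse_normal,
    rank_normalize,
)
from credset.simulate import SimConfig, simulate_eqtl_dataset


class TestExpressionFilters:
    def expr(self, below_in):
        # 10 samples; one feature with `below_in` samples under 1 count
        vals = np.full(10, 5.0)
        vals[:below_in] = 0.2
        return pd.DataFrame([vals], index=["f"], columns=[f"s{i}" for i in range(10)])

    def test_thirty_percent_below_threshold_excluded(self):
        assert len(filter_low_expression(self.expr(3))) == 0

    def test_twenty_percent_exactly_is_kept(self):
        assert len(filter_low_expression(self.expr(2))) == 1

    def test_all_expressed_identity(self):
        m = self.expr(0)
        pd.testing.assert_frame_equal(filter_low_expression(m), m)

    def test_library_size_scaling_hits_target_total(self):
        m = pd.DataFrame(np.random.default_rng(0).poisson(50, (20, 4)).astype(float))
        scaled = normalize_library_size(m, target_total=1e6)
        assert np.allclose(scaled.sum(axis=0), 1e6)


class TestRankInverseNormal:
    def test_closed_form_three_values(self):
        out = rank_inverse_normal([3.0, 1.0, 2.0])
        expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
        assert np.allclose(out, expected, atol=1e-12)
        assert round(out[0], 4) == 0.9674

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, size=50)
        assert np.allclose(rank_inverse_normal(x), rank_inverse_normal(np.log(x)))
        assert np.allclose(rank_inverse_normal(x), rank_inverse_normal(x**3))

    def test_ties_get_average_rank(self):
        out = rank_inverse_normal([1.0, 1.0, 2.0, 3.0])
        assert out[0] == out[1]

    def test_output_symmetric_mean_zero(self):
        out = rank_inverse_normal(np.arange(20.0))
        assert abs(out.mean()) < 1e-9

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_inverse_normal(np.ones(5))

    def test_matrix_version_normalizes_each_feature(self):
        m = pd.DataFrame(
            np.random.default_rng(3).gamma(2, size=(4, 30)),
            index=list("abcd"),
        )
        out = rank_normalize(m)
        assert out.shape == m.shape
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)


class TestCisPairs:
    def setup_method(self):
        self.features = pd.DataFrame(
            {"feature_id": ["g"], "chrom": ["chr1"], "tss": [1_000_000]}
        )

    def variants(self, *pos, chrom="chr1"):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(pos))],
                "chrom": chrom,
                "pos": list(pos),
            }
        )

    def test_100kb_boundary_inclusive(self):
        pairs = cis_pairs(self.features, self.variants(1_100_000), "gene_window_100kb")
        assert len(pairs) == 1

    def test_100kb_plus_one_excluded(self):
        pairs = cis_pairs(self.features, self.variants(1_100_001), "gene_window_100kb")
        assert len(pairs) == 0

    def test_1mb_tss_flank(self):
        v = self.variants(2_000_000, 2_000_001)
        assert len(cis_pairs(self.features, v, "tss_flank_1mb")) == 1

    def test_other_chromosome_excluded_at_zero_distance(self):
        v = self.variants(1_000_000, chrom="chr2")
        assert len(cis_pairs(self.features, v, "gene_window_100kb")) == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            cis_pairs(self.features, self.variants(1), "nearest")


def normal_equations_oracle(y, X):
    """From-scratch OLS: beta, se, t, p for column 1 of X."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    return beta[1], se, t, 2 * stats.t.sf(abs(t), df)


class TestFitCisEqtl:
    def test_exact_fit_reports_beta_and_floor_p(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=50).astype(float)
        res = fit_cis_eqtl(2.0 * g, g)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert 0 < res.p <= 1e-200

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 80
            g = rng.binomial(2, 0.4, size=n).astype(float)
            cov = pd.DataFrame({"age": rng.normal(50, 10, n), "sex": rng.integers(0, 2, n)})
            y = 0.4 * g + 0.02 * cov["age"].to_numpy() + rng.normal(size=n)
            res = fit_cis_eqtl(y, g, cov)
            X = np.column_stack([np.ones(n), g, cov.to_numpy(dtype=float)])
            b, se, t, p = normal_equations_oracle(y, X)
            assert res.beta == pytest.approx(b, rel=1e-10)
            assert res.se == pytest.approx(se, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-8)

    def test_collinear_design_rejected_naming_column(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, size=40).astype(float)
        cov = pd.DataFrame({"dup": g})
        with pytest.raises(ValueError, match="dup|dosage"):
            fit_cis_eqtl(rng.normal(size=40), g, cov)

    def test_missing_values_dropped_pairwise_complete(self):
        g = np.array([0.0, 1, 2, 1, 0, 2, 1, 0, 1, 2])
        y = np.array([0.1, 1.2, 2.1, np.nan, 0.0, 1.9, 1.1, 0.2, 0.9, 2.2])
        res = fit_cis_eqtl(y, g)
        assert res.n == 9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            fit_cis_eqtl([1.0, 2.0], [0.0, 1.0])

    def test_covariate_adjustment_removes_confounding(self):
        # age drives expression; dosage correlates with age by construction
        rng = np.random.default_rng(11)
        n = 300
        age = rng.normal(50, 10, n)
        g = (age > 50).astype(float) + rng.binomial(1, 0.3, n)
        y = 0.1 * age + rng.normal(size=n)
        naive = fit_cis_eqtl(y, g)
        adjusted = fit_cis_eqtl(y, g, pd.DataFrame({"age": age}))
        assert naive.p < 1e-6  # confounded: spurious association
        assert abs(adjusted.beta) < abs(naive.beta)


class TestCisEqtlModel:
    def test_scan_recovers_simulated_effects(self):
        cfg = SimConfig(n_individuals=300, n_genes=6, eqtl_beta=0.8, maf=0.3, seed=9)
        data = simulate_eqtl_dataset(cfg)
        res = CisEqtlModel(
            data.expression, data.features, data.genotypes, data.variants,
            data.covariates, "tss_flank_1mb",
        ).fit()
        assert len(res.table) == 6  # one cis variant per gene
        assert (res.table["p"] < 1e-4).all()
        assert res.table["beta"].mean() == pytest.approx(0.8, abs=0.15)
        assert "cis-eQTL scan" in res.summary()

    def test_bonferroni_column_bounded(self):
        cfg = SimConfig(n_individuals=120, n_genes=3, eqtl_beta=0.0, seed=10)
        data = simulate_eqtl_dataset(cfg)
        res = CisEqtlModel(
            data.expression, data.features, data.genotypes, data.variants,
            data.covariates, "tss_flank_1mb",
        ).fit()
        adj = res.bonferroni()
        assert ((adj["p_bonferroni"] >= adj["p"] - 1e-15) & (adj["p_bonferroni"] <= 1)).all()


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert eqtl_power(PowerSpec(100, 0.3, 0.0, 0.05)) == pytest.approx(0.05)

    def test_huge_effect_saturates(self):
        assert eqtl_power(PowerSpec(10_000, 0.5, 1.0, 1e-7)) > 0.9999

    def test_monte_carlo_oracle_n100_maf03_beta05(self):
        # vectorised simulation oracle: 20,000 regressions of y on g
        rng = np.random.default_rng(12)
        reps, n = 20_000, 100
        g = rng.binomial(2, 0.3, size=(reps, n)).astype(float)
        y = 0.5 * g + rng.normal(size=(reps, n))
        gc = g - g.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        bhat = (gc * yc).sum(axis=1) / (gc * gc).sum(axis=1)
        resid = yc - bhat[:, None] * gc
        se = np.sqrt(resid.pow if False else (resid**2).sum(axis=1) / (n - 2) / (gc * gc).sum(axis=1))
        tstat = bhat / se
        crit = stats.t.ppf(0.975, n - 2)
        mc_power = float((np.abs(tstat) > crit).mean())
        assert eqtl_power(PowerSpec(100, 0.3, 0.5, 0.05)) == pytest.approx(mc_power, abs=0.015)

    def test_monotone_in_n_beta_and_heterozygosity(self):
        base = eqtl_power(PowerSpec(200, 0.2, 0.3, 1e-4))
        assert eqtl_power(PowerSpec(400, 0.2, 0.3, 1e-4)) > base
        assert eqtl_power(PowerSpec(200, 0.2, 0.5, 1e-4)) > base
        assert eqtl_power(PowerSpec(200, 0.4, 0.3, 1e-4)) > base

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(0, 0.3, 0.5, 0.05)
        with pytest.raises(ValueError):
            PowerSpec(100, 1.5, 0.5, 0.05)
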