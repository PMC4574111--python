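"""Statistics: transforms, normality, correlations, GLS factoring, regressions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rhythmbat import analysis
from rhythmbat.analysis import (
    RHYTHM_MEASURES,
    DissociationModel,
    UnderpoweredError,
    apply_exclusions,
    correlation_matrix,
    gls_factor_analysis,
    hierarchical_regression,
    jarque_bera,
    rau_transform,
    transform_pipeline,
)


class TestRau:
    def test_fixed_points(self):
        assert rau_transform(0.5) == pytest.approx(50.0)
        assert rau_transform(0.0) == pytest.approx(-23.0)
        assert rau_transform(1.0) == pytest.approx(123.0)

    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_strictly_increasing(self, p):
        assert rau_transform(p + 0.001) > rau_transform(p)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rau_transform(1.2)
        with pytest.raises(ValueError):
            rau_transform([-0.1, 0.5])


class TestJarqueBera:
    def test_null_point(self):
        # symmetric 8-point sample with kurtosis exactly 3:
        # {±(1+sqrt(2)), ±1, 0 x4} solves n(1+a^4)/(2(1+a^2)^2) = 3 for n=8
        a = 1.0 + math.sqrt(2.0)
        x = np.array([-a, -1.0, 0.0, 0.0, 0.0, 0.0, 1.0, a])
        jb, p = jarque_bera(x)
        assert jb == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_moment_formula(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=200)
        jb, p = jarque_bera(x)
        n = x.size
        m = x - x.mean()
        s = np.mean(m**3) / np.mean(m**2) ** 1.5
        k = np.mean(m**4) / np.mean(m**2) ** 2
        expected = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
        assert jb == pytest.approx(expected)
        assert p < 0.001  # exponential data are decisively non-normal

    def test_normal_sample_passes(self):
        x = np.random.default_rng(1).normal(size=1000)
        _, p = jarque_bera(x)
        assert p > 0.01

    def test_guards(self):
        with pytest.raises(UnderpoweredError):
            jarque_bera(np.arange(5.0))
        with pytest.raises(ValueError):
            jarque_bera(np.ones(20))


def _clean_table(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "metronome_variability": 0.05 + 0.005 * rng.normal(size=n),
            "adaptation_error_ms": 20.0 + 2.0 * rng.normal(size=n),
            "drumalong_pct": 80.0 + 3.0 * rng.normal(size=n),
            "memory_pct": 70.0 + 3.0 * rng.normal(size=n),
            "tempo_deviation_ms": np.abs(rng.normal(size=n)),
        },
        index=[f"p{i:02d}" for i in range(n)],
    )


class TestExclusions:
    def test_outlier_on_any_measure_excluded(self):
        table = _clean_table()
        table.loc["p03", "memory_pct"] = 200.0  # far beyond 3 SD of the cohort
        z = (200.0 - table["memory_pct"].mean()) / table["memory_pct"].std(ddof=1)
        assert z > 3.0  # the construction really clears the threshold
        kept, log = apply_exclusions(table)
        assert "p03" not in kept.index
        assert log == [("p03", "memory_pct > 3 SD from mean")]

    def test_tempo_deviation_rule(self):
        table = _clean_table()
        table.loc["p07", "tempo_deviation_ms"] = 38.7
        kept, log = apply_exclusions(table)
        assert "p07" not in kept.index
        assert ("p07", "mean tempo deviation > 5 ms") in log

    def test_no_exclusions_on_clean_table(self):
        kept, log = apply_exclusions(_clean_table())
        assert len(kept) == 20
        assert log == []

    def test_too_small(self):
        with pytest.raises(UnderpoweredError):
            apply_exclusions(_clean_table().head(3))


class TestTransformPipeline:
    def test_transforms_applied(self):
        table = _clean_table()
        out, applied = transform_pipeline(table)
        assert np.allclose(out["metronome_variability"],
                           np.log(table["metronome_variability"]))
        assert np.allclose(out["drumalong_pct"],
                           rau_transform(table["drumalong_pct"] / 100.0))
        assert out["adaptation_error_ms"].equals(table["adaptation_error_ms"])
        assert out["memory_pct"].equals(table["memory_pct"])
        assert applied["metronome_variability"] == "log"
        assert applied["drumalong_pct"] == "rau"

    def test_refuses_double_transform(self):
        out, _ = transform_pipeline(_clean_table())
        with pytest.raises(ValueError):
            transform_pipeline(out)

    def test_nonpositive_variability_rejected(self):
        table = _clean_table()
        table.loc["p00", "metronome_variability"] = 0.0
        with pytest.raises(ValueError):
            transform_pipeline(table)

    def test_normalizes_skewed_variability(self):
        # lognormal variability: decisively non-normal raw, normal after log
        rng = np.random.default_rng(3)
        table = _clean_table(n=200, seed=3)
        table["metronome_variability"] = np.exp(rng.normal(-3.0, 0.5, size=200))
        _, p_raw = jarque_bera(table["metronome_variability"])
        out, _ = transform_pipeline(table)
        _, p_log = jarque_bera(out["metronome_variability"])
        assert p_raw < 0.01 < p_log


class TestCorrelationMatrix:
    def test_toy_example(self):
        # points (1,2),(2,1),(3,4),(4,3): cross-deviation sum 3, each
        # variance sum 5, so r = 3/5 = 0.6
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 1.0, 4.0, 3.0]})
        r, p = correlation_matrix(table, columns=["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(0.6)
        assert r.loc["x", "x"] == 1.0
        assert (r.values == r.values.T).all()

    def test_affine_invariance(self):
        table = _clean_table()[RHYTHM_MEASURES]
        r1, _ = correlation_matrix(table)
        scaled = table * [2.0, 0.5, 10.0, 3.0] + [1.0, -5.0, 0.0, 100.0]
        r2, _ = correlation_matrix(scaled)
        assert np.allclose(r1.values, r2.values)

    def test_guards(self):
        table = _clean_table()
        table["memory_pct"] = 70.0
        with pytest.raises(ValueError):
            correlation_matrix(table)
        with pytest.raises(UnderpoweredError):
            correlation_matrix(_clean_table().head(3))


def _block_model(h=(0.8, 0.7, 0.6)):
    lam = np.zeros((6, 2))
    lam[:3, 0] = h
    lam[3:, 1] = h
    psi = 1.0 - (lam**2).sum(axis=1)
    sigma = lam @ lam.T + np.diag(psi)
    return lam, psi, sigma


class TestFactorAnalysis:
    def test_exact_recovery_identified_case(self):
        # 6 measures / 2 factors has positive df; a noiseless two-block
        # correlation matrix must be recovered exactly
        lam, psi, sigma = _block_model()
        res = gls_factor_analysis(sigma, n_factors=2)
        assert res.objective == pytest.approx(0.0, abs=1e-8)
        assert res.degrees_of_freedom == 4
        assert not res.heywood
        assert np.allclose(np.sort(res.uniquenesses.values), np.sort(psi), atol=1e-4)
        got = np.sort(np.abs(res.loadings.values).max(axis=1))
        assert np.allclose(got, np.sort(np.tile([0.8, 0.7, 0.6], 2)), atol=1e-4)
        # simple structure: cross-loadings vanish
        assert np.abs(res.loadings.values).min(axis=1).max() < 1e-3
        assert res.variance_explained == pytest.approx((lam**2).sum() / 6.0, abs=1e-4)

    def test_varimax_preserves_communalities(self):
        _, _, sigma = _block_model()
        res = gls_factor_analysis(sigma, n_factors=2)
        rot = (res.loadings.values**2).sum(axis=1)
        unrot = (res.unrotated_loadings.values**2).sum(axis=1)
        assert np.allclose(rot, unrot, atol=1e-10)

    def test_crosscheck_against_statsmodels_ml(self):
        from statsmodels.multivariate.factor import Factor

        _, _, sigma = _block_model()
        sm = Factor(corr=pd.DataFrame(sigma), n_factor=2, method="ml").fit()
        sm_rot = sm.rotate("varimax") or sm
        res = gls_factor_analysis(sigma, n_factors=2)
        # factor congruence up to column order and sign
        a = res.loadings.values
        b = sm.loadings if sm_rot is None else sm.loadings
        congr = np.abs(a.T @ b) / (
            np.linalg.norm(a, axis=0)[:, None] * np.linalg.norm(b, axis=0)[None, :]
        )
        assert congr.max(axis=1).min() > 0.999

    def test_one_factor_and_guards(self):
        _, _, sigma = _block_model()
        res = gls_factor_analysis(sigma, n_factors=1)
        assert res.loadings.shape == (6, 1)
        with pytest.raises(ValueError):
            gls_factor_analysis(sigma, n_factors=6)
        with pytest.raises(ValueError):
            gls_factor_analysis(np.ones((3, 3)))  # singular

    def test_sign_convention(self):
        _, _, sigma = _block_model()
        res = gls_factor_analysis(sigma, n_factors=2)
        for col in res.loadings:
            v = res.loadings[col].values
            assert v[np.argmax(np.abs(v))] > 0


class TestHierarchicalRegression:
    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(8)
        n = 40
        x1 = rng.normal(size=(n, 2))
        x2 = rng.normal(size=(n, 1))
        y = x1 @ [1.0, -0.5] + 0.8 * x2[:, 0] + rng.normal(size=n)

        def oracle_r2(xmat):
            x = np.column_stack([np.ones(n), xmat])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            return 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)

        res = hierarchical_regression(y, x1, x2)
        assert res.r2_step1 == pytest.approx(oracle_r2(x1))
        assert res.r2_full == pytest.approx(oracle_r2(np.column_stack([x1, x2])))
        assert res.delta_r2 == pytest.approx(res.r2_full - res.r2_step1)
        q, df2 = 1, n - 3 - 1
        f = (res.delta_r2 / q) / ((1 - res.r2_full) / df2)
        assert res.f_change == pytest.approx(f)
        assert 0.0 < res.p_change < 1.0

    def test_delta_r2_nonnegative(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = 30
            y = rng.normal(size=n)
            res = hierarchical_regression(
                y, rng.normal(size=(n, 2)), rng.normal(size=(n, 1))
            )
            assert res.delta_r2 >= -1e-12

    def test_irrelevant_step2_adds_nothing(self):
        n = 50
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=(n, 1))
        y = 2.0 * x1[:, 0]  # fully explained at step 1
        res = hierarchical_regression(y + 1e-6 * rng.normal(size=n), x1,
                                      rng.normal(size=(n, 1)))
        assert res.r2_step1 > 0.999999
        assert res.delta_r2 < 1e-6

    def test_guards(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 1))
        with pytest.raises(ValueError):
            hierarchical_regression(rng.normal(size=20), x, 2.0 * x)  # collinear
        with pytest.raises(UnderpoweredError):
            hierarchical_regression(np.arange(4.0), np.ones((4, 1)), np.ones((4, 1)))


class TestDissociationModel:
    def test_fit_on_default_cohort(self, scores65):
        res = DissociationModel(scores65).fit()
        assert res.n_input == 65
        assert 4 <= res.n_analyzed <= 65
        assert set(res.within_cluster_r) == {"beat", "memory"}
        assert res.corr_r.shape == (4, 4)
        assert res.factor.loadings.shape == (4, 2)
        assert len(res.hierarchical) == 2
        assert np.isfinite(res.normality.values).all()
        text = res.summary()
        assert "Pearson correlations" in text
        assert "GLS factor analysis" in text
        assert "Cluster structure" in text

    def test_from_csv_roundtrip(self, scores65, tmp_path):
        path = tmp_path / "scores.csv"
        scores65.to_csv(path)
        res = DissociationModel.from_csv(path).fit()
        direct = DissociationModel(scores65).fit()
        assert np.allclose(res.corr_r.values, direct.corr_r.values)

    def test_transform_switch(self, scores65):
        raw = DissociationModel(scores65, transform=False).fit()
        assert raw.transforms_applied["metronome_variability"] == "none"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            DissociationModel(pd.DataFrame({"metronome_variability": [1.0]}))

    def test_plot(self, scores65, tmp_path):
        out = tmp_path / "scatter.png"
        analysis.plot_score_scatter(scores65, out)
        assert out.stat().st_size > 0
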