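"""FDA, PLS / kernel PLS, and seafood correlations."""

import numpy as np
import pytest
from scipy import stats

from fattyroc.core_data import ANALYTES, CohortTable, SubjectRecord
from fattyroc.multivariate import fda_fit, pls_regress, seafood_correlation

from conftest import make_record


def table_from_arrays(x_asd, x_neu, variables=("AA", "DGLA")):
    """CohortTable from raw score arrays.

    Columns are shifted by a common per-column constant so every stored
    concentration is nonnegative; FDA (scatter matrices and mean
    differences) is translation invariant, so oracles computed on the
    raw arrays remain valid.
    """
    x_asd = np.atleast_2d(np.asarray(x_asd, dtype=float))
    x_neu = np.atleast_2d(np.asarray(x_neu, dtype=float))
    lo = np.minimum(x_asd.min(axis=0), x_neu.min(axis=0))
    shift = np.where(lo < 0, -lo + 1.0, 0.0)
    records = []
    for i, row in enumerate(x_asd + shift):
        records.append(
            SubjectRecord(
                f"a{i}", "ASD", concentrations=dict(zip(variables, map(float, row)))
            )
        )
    for i, row in enumerate(x_neu + shift):
        records.append(
            SubjectRecord(
                f"n{i}", "NEU", concentrations=dict(zip(variables, map(float, row)))
            )
        )
    return CohortTable(records=records)


class TestFda:
    def test_hand_worked_two_variable_oracle(self):
        """3+3-point instance: w must match the closed-form 2x2 solve
        of S_W^{-1} (m1 - m0), computed here with the explicit adjugate
        inverse, to 1e-10 (up to scale)."""
        x_asd = np.array([[2.0, 1.0], [3.0, 2.0], [4.0, 3.0]])
        x_neu = np.array([[0.0, 0.0], [1.0, 1.5], [0.5, 0.5]])
        t = table_from_arrays(x_asd, x_neu)
        model = fda_fit(t, variables=("AA", "DGLA"), ridge=0.0, standardize=False)

        m1, m0 = x_asd.mean(axis=0), x_neu.mean(axis=0)
        sw = np.zeros((2, 2))
        for block, m in ((x_asd, m1), (x_neu, m0)):
            d = block - m
            sw += d.T @ d
        det = sw[0, 0] * sw[1, 1] - sw[0, 1] * sw[1, 0]
        inv = np.array([[sw[1, 1], -sw[0, 1]], [-sw[1, 0], sw[0, 0]]]) / det
        w_hand = inv @ (m1 - m0)
        w_hand /= np.linalg.norm(w_hand)
        sign = np.sign(w_hand @ model.weights)
        assert np.allclose(model.weights, sign * w_hand, atol=1e-10)

    def test_separable_clouds_give_high_c(self, rng):
        x_asd = rng.standard_normal((40, 2)) + 8.0
        x_neu = rng.standard_normal((40, 2))
        model = fda_fit(table_from_arrays(x_asd, x_neu), variables=("AA", "DGLA"))
        assert model.score_c_statistic.c_statistic > 0.99

    def test_scores_invariant_to_affine_rescaling(self, rng):
        x_asd = rng.standard_normal((30, 2)) + [0.5, 0.2]
        x_neu = rng.standard_normal((25, 2))
        base = fda_fit(table_from_arrays(x_asd, x_neu), variables=("AA", "DGLA"),
                       ridge=0.0, standardize=False)
        scaled = fda_fit(
            table_from_arrays(x_asd * [10.0, 0.2], x_neu * [10.0, 0.2]),
            variables=("AA", "DGLA"), ridge=0.0, standardize=False,
        )
        a = np.concatenate([base.scores_asd, base.scores_neu])
        b = np.concatenate([scaled.scores_asd, scaled.scores_neu])
        # scores match up to an affine map (scale and sign)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) > 1 - 1e-9
        assert base.score_c_statistic.c_statistic == pytest.approx(
            scaled.score_c_statistic.c_statistic, abs=1e-9
        )

    def test_matches_sklearn_lda_direction(self, rng):
        """Independent cross-check: sklearn's LDA coefficient vector is
        proportional to the FDA direction."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x = rng.standard_normal((60, 4))
        y = np.array([1] * 30 + [0] * 30)
        x[y == 1] += [0.8, 0.2, -0.3, 0.0]
        t = table_from_arrays(x[y == 1], x[y == 0],
                              variables=("AA", "DGLA", "DHA", "EPA"))
        model = fda_fit(t, variables=("AA", "DGLA", "DHA", "EPA"),
                        ridge=0.0, standardize=False)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(x, y)
        w_ref = lda.coef_.ravel() / np.linalg.norm(lda.coef_)
        sign = np.sign(w_ref @ model.weights)
        assert np.allclose(model.weights, sign * w_ref, atol=1e-6)

    def test_score_c_matches_optimal_projection_for_shared_covariance(self):
        """For two multivariate normals with shared covariance the FDA
        score C equals the univariate C of the optimal (Mahalanobis)
        projection within 0.01 at n = 5000."""
        from fattyroc.density import c_statistic

        rng = np.random.default_rng(31)
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        delta = np.array([0.5, 0.3])
        chol = np.linalg.cholesky(cov)
        x_neu = rng.standard_normal((5000, 2)) @ chol.T
        x_asd = rng.standard_normal((5000, 2)) @ chol.T + delta
        model = fda_fit(table_from_arrays(x_asd, x_neu), variables=("AA", "DGLA"))
        w_opt = np.linalg.solve(cov, delta)
        c_opt = c_statistic(x_asd @ w_opt, x_neu @ w_opt, method="empirical")
        assert model.score_c_statistic.c_statistic == pytest.approx(
            c_opt.c_statistic, abs=0.01
        )

    def test_singular_scatter_without_ridge_errors(self):
        x_asd = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # collinear
        x_neu = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        t = table_from_arrays(x_asd, x_neu)
        with pytest.raises(ValueError, match="ridge"):
            fda_fit(t, variables=("AA", "DGLA"), ridge=0.0, standardize=False)

    def test_too_few_complete_records_errors(self, small_table):
        tiny = small_table.subset(lambda r: r.subject_id in ("a1", "n1", "n2"))
        with pytest.raises(ValueError, match=">= 2"):
            fda_fit(tiny, variables=("AA", "DGLA"))


def severity_table(rng, n=40, linear=True):
    records = []
    for i in range(n):
        aa = 20 + rng.standard_normal()
        dgla = 2.2 + 0.3 * rng.standard_normal()
        y = (2.0 * aa if linear else rng.standard_normal() * 5 + 50)
        records.append(
            SubjectRecord(
                f"s{i}",
                "ASD" if i % 2 else "NEU",
                concentrations={"AA": aa, "DGLA": dgla},
                severity_scores={"instrument": float(y)},
            )
        )
    return CohortTable(records=records)


class TestPls:
    def test_exact_linear_relation_gives_r2_one(self, rng):
        # y exactly linear in the single predictor: one component fits it
        t = severity_table(rng, linear=True)
        m = pls_regress(t, ("AA",), "instrument", n_components=1)
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_linear_kernel_matches_linear_pls(self, rng):
        """Kernel PLS with a linear Gram matrix reproduces NIPALS PLS
        fitted values (both project y onto the same Krylov space)."""
        from fattyroc.multivariate import (
            _center_gram,
            _kernel_pls1_fitted,
            _nipals_pls1_fitted,
        )

        x = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        lin = _nipals_pls1_fitted(xc.copy(), yc.copy(), 2)
        ker = _kernel_pls1_fitted(_center_gram(x @ x.T), yc.copy(), 2)
        assert np.allclose(lin, ker, atol=1e-8)

    def test_full_components_reproduce_least_squares(self, rng):
        from fattyroc.multivariate import _nipals_pls1_fitted

        x = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        xc, yc = x - x.mean(axis=0), y - y.mean()
        fitted = _nipals_pls1_fitted(xc.copy(), yc.copy(), 4)
        beta = np.linalg.lstsq(xc, yc, rcond=None)[0]
        assert np.allclose(fitted, xc @ beta, atol=1e-8)

    def test_matches_sklearn_pls_fitted_values(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        t = severity_table(rng, linear=False)
        m = pls_regress(t, ("AA", "DGLA"), "instrument", n_components=2)
        x = np.array([[r.get("AA"), r.get("DGLA")] for r in t.records])
        y = np.array([r.severity_scores["instrument"] for r in t.records])
        ref = PLSRegression(n_components=2, scale=False).fit(x, y)
        assert np.allclose(m.fitted, ref.predict(x).ravel(), atol=1e-8)

    def test_independent_severity_has_poor_loo_r2(self):
        """Severity unrelated to the panel: leave-one-out R² stays low."""
        vals = []
        for seed in range(5):
            t = severity_table(np.random.default_rng(seed), linear=False)
            m = pls_regress(t, ("AA", "DGLA"), "instrument", n_components=2, loo=True)
            vals.append(m.r_squared_loo)
        assert max(vals) <= 0.1

    def test_too_many_components_errors(self, rng):
        t = severity_table(rng)
        with pytest.raises(ValueError, match="n_components"):
            pls_regress(t, ("AA", "DGLA"), "instrument", n_components=10)

    def test_requires_enough_records(self, small_table):
        with pytest.raises(ValueError, match=">= 10"):
            pls_regress(small_table, ("AA",), "absent", n_components=1)


class TestSeafoodCorrelation:
    def test_near_identity_signal(self, rng):
        records = []
        for i in range(30):
            sea = float(rng.poisson(4))
            records.append(
                make_record(
                    f"s{i}",
                    "ASD" if i % 2 else "NEU",
                    {"DHA": sea + 0.001 * rng.standard_normal()},
                    seafood_meals_per_month=sea,
                )
            )
        out = seafood_correlation(CohortTable(records=records), analytes=("DHA",))
        assert out.loc["DHA", "pooled"] > 0.99

    def test_hand_computed_pearson(self):
        sea = [1.0, 2.0, 3.0, 4.0, 5.0]
        dha = [3.0, 3.5, 3.2, 4.1, 4.4]
        records = [
            make_record(f"s{i}", "ASD", {"DHA": d}, seafood_meals_per_month=s)
            for i, (d, s) in enumerate(zip(dha, sea))
        ]
        out = seafood_correlation(
            CohortTable(records=records), groups=("ASD",), analytes=("DHA",)
        )
        x, y = np.array(dha), np.array(sea)
        r_hand = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert out.loc["DHA", "ASD"] == pytest.approx(r_hand, abs=1e-12)

    def test_insufficient_pairs_warns_and_sets_missing(self, rng):
        records = [
            make_record("s1", "ASD", seafood_meals_per_month=1.0),
            make_record("s2", "ASD", seafood_meals_per_month=2.0),
        ]
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = seafood_correlation(
                CohortTable(records=records), groups=("ASD",), analytes=("AA",)
            )
        assert np.isnan(out.loc["AA", "ASD"])

    def test_spearman_option_is_rank_based(self, rng):
        records = []
        for i in range(20):
            sea = float(i)
            records.append(
                make_record(f"s{i}", "NEU", {"DHA": np.exp(0.3 * i)},
                            seafood_meals_per_month=sea)
            )
        out = seafood_correlation(
            CohortTable(records=records), groups=("NEU",), analytes=("DHA",),
            method="spearman",
        )
        assert out.loc["DHA", "NEU"] == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generator_targets(self, paper_table):
        out = seafood_correlation(paper_table, analytes=("DHA", "EPA"))
        assert out.loc["DHA", "pooled"] == pytest.approx(0.374, abs=0.15)
        assert out.loc["EPA", "pooled"] == pytest.approx(0.393, abs=0.15)
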