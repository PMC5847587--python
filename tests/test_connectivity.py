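"""Fisher-z matrices, network summaries, partial rank correlations, OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from devfmri.connectivity import (
    fisher_z,
    fisher_z_matrix,
    ols_regression,
    partial_rank_correlation,
    summarize_network_correlations,
)
from devfmri.prep import InputError
from devfmri.rois import roi_table, RoiDef

from conftest import make_roiset


def small_roi_table():
    return roi_table(
        [
            RoiDef("A1", "ToM", "R", (1, 1, 1), 9.0, "A2"),
            RoiDef("A2", "ToM", "L", (-1, 1, 1), 9.0, "A1"),
            RoiDef("A3", "ToM", "M", (0, 2, 1), 9.0),
            RoiDef("B1", "Pain", "R", (2, 2, 2), 9.0),
            RoiDef("B2", "Pain", "L", (-2, 2, 2), 9.0),
        ]
    )


def zmat_from(values: dict) -> pd.DataFrame:
    names = ["A1", "A2", "A3", "B1", "B2"]
    m = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), v in values.items():
        m.loc[a, b] = m.loc[b, a] = v
    return m


class TestFisherZ:
    def test_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert float(fisher_z(0.5)) == pytest.approx(0.5493, abs=1e-4)

    def test_perfect_correlation_capped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) > 10

    @given(r=st.floats(-0.999, 0.999))
    @settings(max_examples=50, derandomize=True)
    def test_odd_and_strictly_monotone(self, r):
        assert fisher_z(-r) == pytest.approx(-float(fisher_z(r)), abs=1e-12)
        eps = 1e-4
        assert fisher_z(min(r + eps, 0.9995)) >= float(fisher_z(r))

    def test_matrix_matches_atanh_of_pearson(self, acq, rng):
        vals = rng.normal(size=(3, acq.n_volumes))
        rs = make_roiset(vals, acq)
        z = fisher_z_matrix(rs)
        sl = acq.analysis_slice
        for i in range(3):
            for j in range(i + 1, 3):
                expected = np.arctanh(
                    np.corrcoef(vals[i, sl], vals[j, sl])[0, 1]
                )
                assert z.iloc[i, j] == pytest.approx(expected, abs=1e-10)
        assert np.allclose(z.values, z.values.T, equal_nan=True)

    def test_pairwise_complete_deletion(self, acq, rng):
        vals = rng.normal(size=(2, acq.n_volumes))
        flags = np.zeros(acq.n_volumes, dtype=bool)
        flags[50:60] = True
        vals[:, flags] = np.nan
        rs = make_roiset(vals, acq, flags=flags)
        z = fisher_z_matrix(rs)
        ok = ~flags
        ok[: acq.discarded_leading] = False
        expected = np.arctanh(np.corrcoef(vals[0, ok], vals[1, ok])[0, 1])
        assert z.iloc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_constant_roi_named_in_error(self, acq, rng):
        vals = rng.normal(size=(2, acq.n_volumes))
        vals[1] = 3.0
        with pytest.raises(InputError, match="roi1"):
            fisher_z_matrix(make_roiset(vals, acq))

    def test_independent_noise_z_small(self, acq):
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(200):
            vals = rng.normal(size=(2, acq.n_volumes))
            z = fisher_z_matrix(make_roiset(vals, acq)).iloc[0, 1]
            hits += abs(z) < 0.3
        assert hits >= 199  # |z| < 0.3 with probability > 0.99


class TestNetworkSummaries:
    def test_hand_computed_example(self):
        z = zmat_from(
            {
                ("A1", "A2"): 0.6, ("A1", "A3"): 0.6, ("A2", "A3"): 0.6,
                ("B1", "B2"): 0.4,
                ("A1", "B1"): 0.1, ("A1", "B2"): 0.1, ("A2", "B1"): 0.1,
                ("A2", "B2"): 0.1, ("A3", "B1"): 0.1, ("A3", "B2"): 0.1,
            }
        )
        s = summarize_network_correlations(z, small_roi_table())
        assert s.within_tom_z == pytest.approx(0.6)
        assert s.within_pain_z == pytest.approx(0.4)
        assert s.across_z == pytest.approx(0.1)

    def test_nonbilateral_excludes_homologous_pair(self):
        z = zmat_from(
            {
                ("A1", "A2"): 0.9, ("A1", "A3"): 0.3, ("A2", "A3"): 0.3,
                ("B1", "B2"): 0.4,
                ("A1", "B1"): 0.0, ("A1", "B2"): 0.0, ("A2", "B1"): 0.0,
                ("A2", "B2"): 0.0, ("A3", "B1"): 0.0, ("A3", "B2"): 0.0,
            }
        )
        s = summarize_network_correlations(z, small_roi_table())
        assert s.within_tom_z == pytest.approx(0.5)
        assert s.within_tom_nonbilateral_z == pytest.approx(0.3)

    def test_roi_order_invariance(self, rng):
        tab = small_roi_table()
        names = tab["name"].tolist()
        z = pd.DataFrame(rng.normal(size=(5, 5)), index=names, columns=names)
        z = (z + z.T) / 2
        s1 = summarize_network_correlations(z, tab)
        perm = rng.permutation(5)
        z2 = z.iloc[perm, perm]
        tab2 = tab.iloc[list(perm)].reset_index(drop=True)
        s2 = summarize_network_correlations(z2, tab2)
        assert s1.within_tom_z == pytest.approx(s2.within_tom_z)
        assert s1.across_z == pytest.approx(s2.across_z)

    def test_missing_network_raises(self):
        tab = small_roi_table()
        only_tom = tab[tab["network"] == "ToM"].reset_index(drop=True)
        z = zmat_from({("A1", "A2"): 0.5, ("A1", "A3"): 0.5, ("A2", "A3"): 0.5})
        with pytest.raises(InputError):
            summarize_network_correlations(z, only_tom)


def brute_force_partial_spearman(x, y, cov):
    """Longhand oracle: rank, residualize by explicit normal equations,
    Pearson by the covariance formula."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    C = np.column_stack([np.ones(len(x))] + [ranks(c) for c in cov])
    ex = rx - C @ np.linalg.solve(C.T @ C, C.T @ rx)
    ey = ry - C @ np.linalg.solve(C.T @ C, C.T @ ry)
    num = np.sum((ex - ex.mean()) * (ey - ey.mean()))
    den = np.sqrt(np.sum((ex - ex.mean()) ** 2) * np.sum((ey - ey.mean()) ** 2))
    return num / den


class TestPartialRankCorrelation:
    def test_identity_with_independent_covariate(self, rng):
        x = rng.normal(size=40)
        res = partial_rank_correlation(x, x, rng.normal(size=40))
        assert res.estimate == pytest.approx(1.0, abs=1e-6)

    def test_covariate_driven_association_removed(self, rng):
        c = rng.normal(size=200)
        x = rng.normal(size=200)
        y = 2 * c + 0.01 * rng.normal(size=200)  # driven by the covariate
        res = partial_rank_correlation(x, y, c)
        assert abs(res.estimate) < 0.15

    @pytest.mark.parametrize("n", [6, 8])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.integers(0, 4, size=n).astype(float)  # ties included
        y = rng.normal(size=n)
        cov = rng.normal(size=n)
        res = partial_rank_correlation(x, y, cov)
        oracle = brute_force_partial_spearman(x, y, [cov])
        assert res.estimate == pytest.approx(oracle, abs=1e-10)

    def test_spearman_cross_checked_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "x": rng.normal(size=50),
                "y": rng.normal(size=50),
                "c": rng.normal(size=50),
            }
        )
        res = partial_rank_correlation(df["x"], df["y"], df["c"])
        ref = pingouin.partial_corr(
            df, x="x", y="y", covar="c", method="spearman"
        )
        assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_no_covariates_equals_plain_rank_correlation(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        sp = partial_rank_correlation(x, y, method="spearman")
        assert sp.estimate == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-10
        )
        kd = partial_rank_correlation(x, y, method="kendall")
        assert kd.estimate == pytest.approx(
            stats.kendalltau(x, y).statistic, abs=1e-10
        )

    def test_constant_input_raises(self):
        with pytest.raises(InputError):
            partial_rank_correlation(np.ones(10), np.arange(10.0))


class TestOlsRegression:
    def test_exact_fit_raw_scale(self):
        x = np.arange(10.0)
        res = ols_regression(
            2 * x + 1, pd.DataFrame({"x": x}), standardize=False
        )
        assert res.b("x") == pytest.approx(2.0, abs=1e-10)
        assert res.b("const") == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        n = 50
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=n)
        res = ols_regression(y, X, standardize=False)
        Xi = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        for i, name in enumerate(["const", "a", "b", "c"]):
            assert res.b(name) == pytest.approx(beta[i], abs=1e-10)

    def test_row_permutation_invariance(self, rng):
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = rng.normal(size=n)
        res1 = ols_regression(y, X)
        perm = rng.permutation(n)
        res2 = ols_regression(y[perm], X.iloc[perm].reset_index(drop=True))
        assert res1.b("a") == pytest.approx(res2.b("a"), abs=1e-10)

    def test_standardized_binary_group_effect_scale(self, rng):
        # A one-s.d. group difference should give |b| near the point-biserial
        # correlation on the standardized scale, not the raw difference.
        g = np.repeat([0.0, 1.0], 50)
        y = g * 2.0 + rng.normal(size=100) * 0.001
        res = ols_regression(y, pd.DataFrame({"g": g}))
        assert res.b("g") == pytest.approx(1.0, abs=0.01)

    def test_collinear_predictors_raise(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(InputError, match="a.*b|collinear"):
            ols_regression(rng.normal(size=20), X)
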