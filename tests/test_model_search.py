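import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoroqspr import descriptor_engine as de
from fluoroqspr import model_search as ms
from fluoroqspr.errors import CorrelationError, DomainError, MissingDescriptorError


def make_table(arr, cols=None, ids=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"x{j}" for j in range(arr.shape[1])]
    ids = ids or [f"c{i:02d}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, columns=cols, index=ids)
    df.index.name = "compound_id"
    return de.DescriptorTable(df)


def brute_force_ranking(X: pd.DataFrame, y: np.ndarray):
    """Independent oracle: pinv solves + hand metric formulas + tuple sort."""
    results = []
    cols = list(X.columns)
    for k in (1, 2):
        for combo in itertools.combinations(cols, k):
            A = np.column_stack([np.ones(len(y)), X[list(combo)].to_numpy()])
            beta = np.linalg.pinv(A) @ y
            resid = y - A @ beta
            ss_res = float(np.sum(resid ** 2))
            ss_tot = float(np.sum((y - np.mean(y)) ** 2))
            r2 = 1 - ss_res / ss_tot
            mae = float(np.mean(np.abs(resid)))
            rmse = float(np.sqrt(np.mean(resid ** 2)))
            results.append((combo, r2, mae, rmse))
    results.sort(key=lambda t: (-t[1], t[2], t[3], len(t[0]), t[0]))
    return results


class TestFitOls:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        m = ms.fit_ols(x, 2 * x + 1, terms=("x",))
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.mae == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_response(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])  # zero covariance with x
        m = ms.fit_ols(x, y, terms=("x",))
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_pinv_oracle(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        m = ms.fit_ols(X, y, terms=("a", "b"))
        A = np.column_stack([np.ones(20), X])
        beta = np.linalg.pinv(A) @ y
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert m.coefficients[0] == pytest.approx(beta[1], abs=1e-10)
        assert m.coefficients[1] == pytest.approx(beta[2], abs=1e-10)

    def test_too_few_observations(self):
        with pytest.raises(DomainError):
            ms.fit_ols(np.array([[1.0, 2.0], [2.0, 1.0]]), np.array([1.0, 2.0]))


class TestMetrics:
    def test_alternating_residuals(self):
        r2, mae, rmse = ms.metrics(np.array([1.0, -1.0, 1.0, -1.0]),
                                   np.array([1.0, 2.0, 3.0, 4.0]))
        assert mae == 1.0 and rmse == 1.0

    def test_uneven_residuals(self):
        _, mae, rmse = ms.metrics(np.array([0.0, 2.0]), np.array([0.0, 1.0]))
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(2.0))

    def test_zero_variance_response(self):
        with pytest.raises(DomainError):
            ms.metrics(np.zeros(4), np.ones(4))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=50))
    def test_rmse_ge_mae(self, resid):
        y = np.arange(len(resid), dtype=float)
        _, mae, rmse = ms.metrics(np.array(resid), y)
        assert rmse >= mae - 1e-9 * max(1.0, mae)


class TestEnumerateModels:
    def test_small_count(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.normal(size=(10, 3)))
        rep = ms.enumerate_models(t, rng.normal(size=10))
        assert rep.n_models == 6

    def test_count_identity(self):
        for d in (3, 10):
            rng = np.random.default_rng(d)
            t = make_table(rng.normal(size=(12, d)))
            rep = ms.enumerate_models(t, rng.normal(size=12))
            assert rep.n_models == d + d * (d - 1) // 2

    def test_exhaustive_term_sets(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.normal(size=(10, 4)))
        rep = ms.enumerate_models(t, rng.normal(size=10))
        got = [frozenset(m.terms) for m in rep.ranked]
        cols = t.descriptor_names
        expected = [frozenset((c,)) for c in cols] + [
            frozenset(p) for p in itertools.combinations(cols, 2)
        ]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_oracle_ranking_agreement(self):
        for seed, (n, d) in enumerate([(8, 3), (12, 5), (10, 6)]):
            rng = np.random.default_rng(seed)
            t = make_table(rng.normal(size=(n, d)))
            y = rng.normal(size=n)
            rep = ms.enumerate_models(t, y)
            oracle = brute_force_ranking(t.values, y)
            assert [m.terms for m in rep.ranked] == [o[0] for o in oracle]
            for m, o in zip(rep.ranked, oracle):
                assert m.r2 == pytest.approx(o[1], abs=1e-10)
                assert m.mae == pytest.approx(o[2], abs=1e-10)
                assert m.rmse == pytest.approx(o[3], abs=1e-10)

    def test_pair_r2_at_least_submodel_r2(self):
        rng = np.random.default_rng(17)
        t = make_table(rng.normal(size=(15, 5)))
        y = rng.normal(size=15)
        rep = ms.enumerate_models(t, y)
        singles = {m.terms[0]: m.r2 for m in rep.ranked if len(m.terms) == 1}
        for m in rep.ranked:
            if len(m.terms) == 2:
                assert m.r2 >= singles[m.terms[0]] - 1e-10
                assert m.r2 >= singles[m.terms[1]] - 1e-10

    def test_rmse_ge_mae_every_model(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(12, 6)))
        rep = ms.enumerate_models(t, rng.normal(size=12))
        for m in rep.ranked:
            assert m.rmse >= m.mae - 1e-12

    def test_noise_descriptor_never_hurts(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(14, 5))
        y = rng.normal(size=14)
        r2_before = ms.enumerate_models(make_table(base), y).best.r2
        widened = np.column_stack([base, rng.normal(size=14)])
        r2_after = ms.enumerate_models(make_table(widened), y).best.r2
        assert r2_after >= r2_before - 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(12, 4))
        y = pd.Series(rng.normal(size=12), index=[f"c{i:02d}" for i in range(12)])
        t = make_table(arr)
        rep = ms.enumerate_models(t, y)
        # permute columns and rows
        perm_cols = ["x2", "x0", "x3", "x1"]
        perm_rows = list(reversed(t.values.index))
        df2 = t.values.loc[perm_rows, perm_cols]
        rep2 = ms.enumerate_models(de.DescriptorTable(df2), y)
        assert {frozenset(m.terms): round(m.r2, 12) for m in rep.ranked} == \
               {frozenset(m.terms): round(m.r2, 12) for m in rep2.ranked}
        assert set(rep.best.terms) == set(rep2.best.terms)

    def test_collinear_pair_flagged_but_counted(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        arr = np.column_stack([x, x * 2.0 + 1e-9 * rng.normal(size=12),
                               rng.normal(size=12)])
        t = make_table(arr)
        rep = ms.enumerate_models(t, rng.normal(size=12))
        assert rep.n_models == 6
        ranked_sets = {frozenset(m.terms) for m in rep.ranked}
        assert frozenset({"x0", "x1"}) not in ranked_sets

    def test_max_terms_limit(self):
        rng = np.random.default_rng(7)
        t = make_table(rng.normal(size=(10, 3)))
        with pytest.raises(DomainError):
            ms.enumerate_models(t, rng.normal(size=10), max_terms=3)


class TestSelectBest:
    def _model(self, terms, r2, mae, rmse):
        return ms.CandidateModel(terms=terms, coefficients=(0.0,) * len(terms),
                                 intercept=0.0, r2=r2, mae=mae, rmse=rmse)

    def test_higher_r2_wins(self):
        a = self._model(("a",), 0.95, 0.2, 0.3)
        b = self._model(("b",), 0.80, 0.1, 0.2)
        assert ms.select_best_from([b, a]) is a

    def test_tie_broken_by_mae(self):
        a = self._model(("a",), 0.9, 0.1, 0.3)
        b = self._model(("b",), 0.9, 0.2, 0.2)
        assert ms.select_best_from([b, a]) is a

    def test_full_tie_prefers_fewer_terms(self):
        one = self._model(("a",), 0.9, 0.1, 0.1)
        two = self._model(("a", "b"), 0.9, 0.1, 0.1)
        assert ms.select_best_from([two, one]) is one

    def test_empty_pool_rejected(self):
        with pytest.raises(DomainError):
            ms.select_best_from([])


class TestPredict:
    def _fitted(self):
        rng = np.random.default_rng(8)
        raw = make_table(rng.uniform(1, 5, size=(12, 3)))
        scaled = de.scale_minmax(raw)
        y = pd.Series(
            2.0 * scaled.values["x0"] - 1.0 * scaled.values["x1"] + 0.5,
            index=scaled.values.index,
        )
        rep = ms.enumerate_models(scaled, y)
        return raw, scaled, y, rep.best

    def test_all_zero_scaled_gives_intercept(self):
        m = ms.CandidateModel(terms=("a", "b"), coefficients=(1.5, -2.0),
                              intercept=0.7, r2=1, mae=0, rmse=0)
        df = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["z"])
        t = de.DescriptorTable(df, scaling={"a": (0.0, 1.0), "b": (0.0, 1.0)})
        assert ms.predict(m, t)["z"] == pytest.approx(0.7)

    def test_training_compound_matches_fitted_value(self):
        raw, scaled, y, best = self._fitted()
        preds = ms.predict(best, scaled)
        cid = scaled.values.index[0]
        expected = best.intercept + sum(
            c * scaled.values.loc[cid, t] for t, c in zip(best.terms, best.coefficients)
        )
        assert preds[cid] == pytest.approx(expected, abs=1e-12)

    def test_raw_table_uses_training_scaling(self):
        raw, scaled, y, best = self._fitted()
        p_raw = ms.predict(best, raw)
        p_scaled = ms.predict(best, scaled)
        assert np.allclose(p_raw.to_numpy(), p_scaled.to_numpy(), atol=1e-10)

    def test_missing_descriptor_listed(self):
        m = ms.CandidateModel(terms=("nope",), coefficients=(1.0,), intercept=0.0,
                              r2=1, mae=0, rmse=0)
        t = make_table(np.ones((8, 2)) * np.arange(8)[:, None])
        with pytest.raises(MissingDescriptorError, match="nope"):
            ms.predict(m, t)

    def test_missing_id_listed(self):
        raw, scaled, y, best = self._fitted()
        with pytest.raises(MissingDescriptorError, match="ghost"):
            ms.predict(best, scaled, ids=["ghost"])

    def test_serialization_round_trip(self, tmp_path):
        _, _, _, best = self._fitted()
        p = tmp_path / "model.json"
        best.save(p)
        back = ms.CandidateModel.load(p)
        assert back.terms == best.terms
        assert back.coefficients == best.coefficients
        assert back.scaling == best.scaling


class TestCorrelate:
    def test_affine_perfect(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, r2 = ms.correlate(a, 2 * a + 5)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_negation(self):
        a = np.array([1.0, 2.0, 5.0])
        r, _ = ms.correlate(a, -a)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=20), rng.normal(size=20)
        r, r2 = ms.correlate(a, b)
        oracle = float(np.sum((a - a.mean()) * (b - b.mean()))
                       / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
        assert r == pytest.approx(oracle, abs=1e-12)
        assert r2 == pytest.approx(oracle ** 2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(CorrelationError):
            ms.correlate(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(CorrelationError):
            ms.correlate(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
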