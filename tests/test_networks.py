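import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emonet.networks import (
    CollinearityError,
    ContemporaneousNetwork,
    DirectedNetwork,
    FitError,
    InsufficientDataError,
    NodeSubset,
    connectivity,
    contemporaneous_from_residuals,
    fit_var,
)
from emonet.simulate import make_spec, scale_lag_matrix, simulate_participant

from conftest import make_panel


def normal_equations_oracle(X, y):
    """Independent OLS: explicitly solve (X'X) b = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def brute_force_partial_corr(R):
    """Partial correlation via the residual-regression definition:
    regress column i and j on all other columns, correlate residuals."""
    k = R.shape[1]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            others = [c for c in range(k) if c not in (i, j)]
            Z = np.column_stack([np.ones(R.shape[0])] + [R[:, c] for c in others])
            ri = R[:, i] - Z @ np.linalg.lstsq(Z, R[:, i], rcond=None)[0]
            rj = R[:, j] - Z @ np.linalg.lstsq(Z, R[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def subset_of(panel, items=None):
    items = items or panel.item_names
    return NodeSubset.from_items(items, panel.item_valence)


class TestFitVar:
    def test_five_node_network_has_25_coefficients(self, random_panel):
        net, _ = fit_var(random_panel, subset_of(random_panel))
        assert net.edges.shape == (5, 5)
        assert net.edges.size == 25

    def test_matches_normal_equations_oracle(self, random_panel):
        net, _ = fit_var(random_panel, subset_of(random_panel))
        V = random_panel.values
        X = np.column_stack([np.ones(V.shape[0] - 1), V[:-1]])
        for i in range(5):
            beta = normal_equations_oracle(X, V[1:, i])
            np.testing.assert_allclose(net.edges[i], beta[1:], atol=1e-8)

    def test_white_noise_off_diagonals_near_zero(self):
        spec = make_spec(5, 0.05, seed=2, scale="continuous")
        panel = simulate_participant(spec, 0.0, T=10000, seed=5)
        net, _ = fit_var(panel, subset_of(panel))
        off = net.edges - np.diag(np.diag(net.edges))
        assert np.abs(off).max() < 0.03

    def test_recovers_known_lag_matrix(self):
        spec = make_spec(5, 0.06, seed=3, scale="continuous")
        gamma = spec.gamma_range[1] * 0.7
        panel = simulate_participant(spec, gamma, T=10000, seed=3)
        net, _ = fit_var(panel, subset_of(panel))
        np.testing.assert_allclose(
            net.edges, scale_lag_matrix(spec.A0, gamma), atol=0.03
        )

    def test_insufficient_data(self):
        panel = make_panel(
            np.random.default_rng(0).standard_normal((5, 5)),
            items=list("abcde"),
            valence={c: "negative" for c in "abcde"},
            scale="continuous",
        )
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            fit_var(panel, subset_of(panel))

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        values = np.column_stack([x, 2 * x, rng.standard_normal(100)])
        panel = make_panel(
            values,
            items=["a", "b", "c"],
            valence={c: "negative" for c in "abc"},
            scale="continuous",
        )
        with pytest.raises(CollinearityError, match="'a' and 'b'"):
            fit_var(panel, subset_of(panel))

    def test_missing_slot_excludes_lag_pairs(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((50, 2))
        values[10, 0] = np.nan  # kills pair (10->11) for all and (9->10) for item a
        panel = make_panel(
            values,
            items=["a", "b"],
            valence={"a": "negative", "b": "negative"},
            scale="continuous",
        )
        net, record = fit_var(panel, subset_of(panel))
        # item a loses t=10 (outcome missing) and t=11 (predictor missing): 47
        # item b loses only t=11: 48; the recorded count is the minimum
        assert net.n_lag_pairs_used == 47
        assert record.rows[1].size == 48
        assert 11 not in record.rows[0] and 11 not in record.rows[1]
        assert 10 not in record.rows[0]  # outcome for item a missing at t=10
        assert 10 in record.rows[1]

    def test_residuals_orthogonal_to_design(self, random_panel):
        _, record = fit_var(random_panel, subset_of(random_panel))
        V = random_panel.values
        for rows, resid in zip(record.rows, record.residuals):
            X = np.column_stack([np.ones(rows.size), V[rows - 1]])
            np.testing.assert_allclose(X.T @ resid, 0, atol=1e-8)


class TestContemporaneous:
    def _record(self, T=400, k=4, seed=0, cov=None):
        rng = np.random.default_rng(seed)
        if cov is None:
            cov = np.eye(k)
        R = rng.multivariate_normal(np.zeros(k), cov, size=T)
        from emonet.networks import ResidualRecord

        rec = ResidualRecord(items=tuple(f"i{j}" for j in range(k)))
        rows = np.arange(1, T + 1)
        for j in range(k):
            rec.rows.append(rows.copy())
            rec.residuals.append(R[:, j])
        return rec, R

    def test_independent_residuals_edges_near_zero(self):
        rec, _ = self._record(T=5000)
        net = contemporaneous_from_residuals(rec)
        assert np.abs(net.edges).max() < 0.05

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_partial_matches_brute_force(self, k):
        cov = np.eye(k) + 0.3
        rec, R = self._record(T=300, k=k, seed=k, cov=cov)
        net = contemporaneous_from_residuals(rec, mode="partial")
        np.testing.assert_allclose(
            net.edges, brute_force_partial_corr(R), atol=1e-10
        )

    def test_zero_order_matches_corrcoef(self):
        rec, R = self._record(T=200, seed=5, cov=np.eye(4) + 0.2)
        net = contemporaneous_from_residuals(rec, mode="zero_order")
        expected = np.corrcoef(R, rowvar=False)
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(net.edges, expected, atol=1e-12)

    def test_symmetry_and_zero_diagonal(self, random_panel):
        _, record = fit_var(random_panel, subset_of(random_panel))
        net = contemporaneous_from_residuals(record)
        np.testing.assert_array_equal(net.edges, net.edges.T)
        assert np.all(np.diag(net.edges) == 0)
        assert np.abs(net.edges).max() <= 1

    def test_alignment_on_common_rows(self):
        """Equations with different row sets are aligned before correlating."""
        rec, R = self._record(T=100, seed=9, cov=np.eye(4) + 0.3)
        # remove some rows from equation 0 only
        keep = np.ones(100, dtype=bool)
        keep[[3, 40, 77]] = False
        rec.rows[0] = rec.rows[0][keep]
        rec.residuals[0] = rec.residuals[0][keep]
        net = contemporaneous_from_residuals(rec)
        assert net.n_rows_used == 97
        np.testing.assert_allclose(
            net.edges, brute_force_partial_corr(R[keep]), atol=1e-10
        )

    def test_too_few_common_rows(self):
        rec, _ = self._record(T=5)
        with pytest.raises(InsufficientDataError):
            contemporaneous_from_residuals(rec)


class TestConnectivity:
    def test_zero_matrix(self):
        net = DirectedNetwork(items=("a", "b"), edges=np.zeros((2, 2)), n_lag_pairs_used=10)
        assert connectivity(net) == 0

    def test_directed_includes_diagonal(self):
        edges = np.array([[0.4, 0.1], [-0.2, 0.3]])
        net = DirectedNetwork(items=("a", "b"), edges=edges, n_lag_pairs_used=10)
        assert connectivity(net) == pytest.approx(0.6)

    def test_contemporaneous_unique_edges(self):
        edges = np.array([[0, 0.5, -0.2], [0.5, 0, 0.1], [-0.2, 0.1, 0]])
        net = ContemporaneousNetwork(items=("a", "b", "c"), edges=edges)
        assert connectivity(net) == pytest.approx(0.4)

    def test_non_finite_edge_rejected(self):
        edges = np.array([[np.nan, 0], [0, 0]])
        net = DirectedNetwork(items=("a", "b"), edges=edges, n_lag_pairs_used=10)
        with pytest.raises(FitError):
            connectivity(net)

    def test_invariant_to_node_ordering(self, random_panel):
        items = list(random_panel.item_names)
        base_sub = subset_of(random_panel, items)
        net, rec = fit_var(random_panel, base_sub)
        c_dir, c_con = connectivity(net), connectivity(contemporaneous_from_residuals(rec))
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = list(rng.permutation(items))
            n2, r2 = fit_var(random_panel, subset_of(random_panel, perm))
            assert connectivity(n2) == pytest.approx(c_dir, abs=1e-10)
            assert connectivity(
                contemporaneous_from_residuals(r2)
            ) == pytest.approx(c_con, abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_connectivity_equals_signed_sum_property(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        edges = rng.standard_normal((k, k))
        net = DirectedNetwork(items=tuple(map(str, range(k))), edges=edges, n_lag_pairs_used=1)
        assert connectivity(net) == edges.sum()
        sym = (edges + edges.T) / 2
        np.fill_diagonal(sym, 0)
        sym = np.clip(sym, -1, 1)
        cnet = ContemporaneousNetwork(items=tuple(map(str, range(k))), edges=sym)
        iu = np.triu_indices(k, 1)
        assert connectivity(cnet) == pytest.approx(sym[iu].sum(), abs=1e-14)


class TestEstimatorConsistency:
    def test_mae_decreases_with_sample_size(self):
        spec = make_spec(5, 0.06, seed=11, scale="continuous")
        gamma = spec.gamma_range[1] * 0.6
        A_true = scale_lag_matrix(spec.A0, gamma)
        maes = []
        for T in (200, 2000, 10000):
            panel = simulate_participant(spec, gamma, T=T, seed=17)
            net, _ = fit_var(panel, subset_of(panel))
            maes.append(np.abs(net.edges - A_true).mean())
        assert maes[0] > maes[1] > maes[2]
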