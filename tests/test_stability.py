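import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from wheatstab.stability import (
    ecovalence,
    rank_correlation_matrix,
    spearman_exact,
    stability_table,
    superiority,
)
from wheatstab.synthetic import SimConfig, simulate_yield_components
from wheatstab.trial_io import env_means


def two_by_two(rows):
    return pd.DataFrame(rows, index=["g1", "g2"], columns=["e1", "e2"])


def interaction_ss(X: np.ndarray) -> float:
    """Brute-force G x E interaction SS of a two-way means table."""
    total = 0.0
    gm = X.mean()
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            total += (X[i, j] - X[i].mean() - X[:, j].mean() + gm) ** 2
    return total


matrices = arrays(
    np.float64, (8, 16),
    elements=st.floats(-100, 100, allow_nan=False, width=64),
)


class TestSuperiority:
    def test_hand_worked_2x2(self):
        P = superiority(two_by_two([[1.0, 2.0], [3.0, 4.0]]))
        assert P["g1"] == pytest.approx(2.0)
        assert P["g2"] == pytest.approx(0.0)

    def test_single_entity_is_its_own_maximum(self):
        m = pd.DataFrame([[5.0, 9.0, 2.0]], index=["g1"])
        assert superiority(m)["g1"] == 0.0

    def test_global_shift_invariance(self):
        m = two_by_two([[1.0, 2.0], [4.0, 3.0]])
        base = superiority(m)
        shifted = superiority(m + 17.5)
        pd.testing.assert_series_equal(base, shifted)


class TestEcovalence:
    def test_additive_table_has_zero_ecovalence(self):
        W = ecovalence(two_by_two([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(W, 0.0, atol=1e-12)

    def test_hand_worked_crossover(self):
        W = ecovalence(two_by_two([[1.0, 2.0], [4.0, 3.0]]))
        assert W["g1"] == pytest.approx(0.5)
        assert W["g2"] == pytest.approx(0.5)

    def test_column_constant_invariance(self):
        m = two_by_two([[1.0, 2.0], [4.0, 3.0]])
        shifted = m + pd.Series({"e1": 5.0, "e2": -3.0})
        pd.testing.assert_series_equal(ecovalence(m), ecovalence(shifted))

    def test_single_row_degenerate(self):
        with pytest.raises(ValueError, match=">= 2"):
            ecovalence(pd.DataFrame([[1.0, 2.0]]))

    @settings(max_examples=50, deadline=None)
    @given(X=matrices)
    def test_sum_equals_interaction_ss(self, X):
        m = pd.DataFrame(X)
        W = ecovalence(m)
        expect = interaction_ss(X)
        assert W.sum() == pytest.approx(expect, rel=1e-10, abs=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(X=matrices, c=st.floats(0.1, 10))
    def test_invariances_and_scaling(self, X, c):
        m = pd.DataFrame(X)
        W = ecovalence(m)
        # add one constant per row and one per column (derived from X itself)
        row_vec = X[:, :1]
        col_vec = X[:1, :]
        shifted = pd.DataFrame(X + row_vec + col_vec)
        np.testing.assert_allclose(ecovalence(shifted), W, atol=1e-6)
        np.testing.assert_allclose(ecovalence(m * c), W * c * c,
                                   rtol=1e-9, atol=1e-9)


class TestStabilityTable:
    def test_additive_simulation_all_w_zero(self):
        cfg = SimConfig(sigma_ge=(0.0,) * 8, residual_sd=0.0,
                        sensitivity_slopes=(1.0,) * 8)
        table, _ = simulate_yield_components(cfg)
        res = stability_table(table, ["GY"], perspective="genotype")
        assert (res["W"].abs() < 1e-10).all()
        # P ordering reverses the mean ordering on an additive table
        assert (res.sort_values("P")["mean"].diff().dropna() <= 1e-9).all()

    def test_best_everywhere_entity_rank_one(self):
        cfg = SimConfig(
            genotype_effects=(3.0, -0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3),
            sigma_ge=(0.0,) * 8, residual_sd=0.05,
            sensitivity_slopes=(1.0,) * 8, seed=5)
        table, _ = simulate_yield_components(cfg)
        res = stability_table(table, ["GY"], perspective="genotype")
        best = res.loc[res["entity"] == "Akteur"]  # first genotype, +3 t/ha
        assert best["P"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert best["rank_P"].iloc[0] == 1

    def test_deterministic_on_fixed_seed(self, yield_table):
        table, _ = yield_table
        a = stability_table(table, ["GY", "GN"], perspective="genotype")
        b = stability_table(table, ["GY", "GN"], perspective="genotype")
        pd.testing.assert_frame_equal(a, b)

    def test_dual_perspective_shapes(self, yield_table):
        table, _ = yield_table
        for persp in ("genotype", "management"):
            res = stability_table(table, ["GY"], perspective=persp)
            assert len(res) == 8
            assert (res["n_environments"] == 16).all()


class TestRankCorrelation:
    def _results(self, vectors):
        rows = []
        for trait, vec in vectors.items():
            for i, v in enumerate(vec):
                rows.append({"entity": f"g{i}", "trait": trait,
                             "perspective": "genotype", "P": v, "W": v})
        return pd.DataFrame(rows)

    def test_identical_vectors_rho_one(self):
        res = self._results({"GY": [1, 2, 3, 4], "GN": [1, 2, 3, 4]})
        rc = rank_correlation_matrix(res, index="P")
        assert rc.rho.loc["GY", "GN"] == pytest.approx(1.0)
        assert rc.rho.loc["GY", "GY"] == 1.0

    def test_reversed_vectors_rho_minus_one(self):
        res = self._results({"GY": [1, 2, 3, 4], "GN": [4, 3, 2, 1]})
        rc = rank_correlation_matrix(res, index="P")
        assert rc.rho.loc["GY", "GN"] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        res = self._results({"GY": [1, 2, 3, 4], "GN": [1, 2, 4, 3]})
        rc = rank_correlation_matrix(res, index="P")
        assert rc.rho.loc["GY", "GN"] == pytest.approx(0.8)

    def test_exact_permutation_p_matches_rho(self):
        rho, p = spearman_exact([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)
        assert 0.0 < p <= 1.0
        rho_t = rank_correlation_matrix(
            self._results({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 5, 4]}),
            index="P", method="exact")
        assert rho_t.rho.loc["a", "b"] == pytest.approx(0.9)

    def test_too_few_entities_rejected(self):
        res = self._results({"GY": [1, 2], "GN": [2, 1]})
        with pytest.raises(ValueError, match=">= 3"):
            rank_correlation_matrix(res)

    def test_matrix_is_symmetric_with_unit_diagonal(self, yield_table):
        table, _ = yield_table
        res = stability_table(table, ["GY", "GN", "TGW", "SN"],
                              perspective="genotype")
        rc = rank_correlation_matrix(res, index="W")
        np.testing.assert_allclose(rc.rho, rc.rho.T)
        np.testing.assert_allclose(np.diag(rc.rho), 1.0)
        assert (rc.rho.abs() <= 1.0 + 1e-12).all().all()
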