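import numpy as np
import pandas as pd
import pytest

from wheatstab.phenospace import (
    DEFAULT_PHENOSPACE_TRAITS,
    pca_scaled,
    project,
    slope_screen,
)

from conftest import make_table


def entity_matrix(data, traits=None):
    traits = traits or [f"t{i}" for i in range(len(data[0]))]
    return pd.DataFrame(data, columns=traits,
                        index=[f"g{i}" for i in range(len(data))])


class TestPcaScaled:
    def test_perfectly_correlated_traits_pc1_everything(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = entity_matrix(np.c_[x, 2 * x + 1])
        space = pca_scaled(m)
        assert space.variance_fraction["PC1"] == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_split_evenly(self):
        # orthogonal design: exactly zero sample correlation
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        space = pca_scaled(entity_matrix(np.c_[x, y]))
        assert space.variance_fraction["PC1"] == pytest.approx(0.5)
        assert space.variance_fraction["PC2"] == pytest.approx(0.5)

    def test_variance_fractions_sum_to_one(self, sim_table):
        table, _ = sim_table
        sub = table[table["trait"].isin(DEFAULT_PHENOSPACE_TRAITS)]
        mat = sub.pivot_table(index="genotype", columns="trait",
                              values="value", aggfunc="mean")
        space = pca_scaled(mat)
        assert space.variance_fraction.sum() == pytest.approx(1.0)
        assert ((space.variance_fraction >= 0)
                & (space.variance_fraction <= 1)).all()

    def test_loadings_orthonormal(self, sim_table):
        table, _ = sim_table
        sub = table[table["trait"].isin(DEFAULT_PHENOSPACE_TRAITS)]
        mat = sub.pivot_table(index="genotype", columns="trait",
                              values="value", aggfunc="mean")
        L = pca_scaled(mat).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_reconstruction_of_centered_input(self):
        rng = np.random.default_rng(1)
        m = entity_matrix(rng.normal(size=(8, 5)))
        space = pca_scaled(m)
        Z = (m - space.means) / space.sds
        recon = space.scores.to_numpy() @ space.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-9)

    def test_zero_variance_trait_named_in_error(self):
        m = entity_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]],
                          traits=["GY", "dead"])
        with pytest.raises(ValueError, match="dead"):
            pca_scaled(m)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        m = entity_matrix(rng.normal(size=(8, 4)))
        s1, s2 = pca_scaled(m), pca_scaled(m)
        pd.testing.assert_frame_equal(s1.loadings, s2.loadings)
        for pc in s1.loadings.columns:
            col = s1.loadings[pc]
            assert col.iloc[np.argmax(col.abs().to_numpy())] > 0


class TestProject:
    def test_training_rows_reproduce_scores(self):
        rng = np.random.default_rng(3)
        m = entity_matrix(rng.normal(size=(8, 4)))
        space = pca_scaled(m)
        proj = project(space, m)
        np.testing.assert_allclose(proj[space.scores.columns], space.scores,
                                   atol=1e-10)

    def test_trait_mean_row_maps_to_origin(self):
        rng = np.random.default_rng(4)
        m = entity_matrix(rng.normal(size=(8, 4)))
        space = pca_scaled(m)
        mean_row = pd.DataFrame([space.means], index=["centroid"])
        proj = project(space, mean_row)
        np.testing.assert_allclose(proj[space.scores.columns].to_numpy(),
                                   0.0, atol=1e-12)

    def test_quadrant_convention(self):
        rng = np.random.default_rng(5)
        m = entity_matrix(rng.normal(size=(8, 3)))
        space = pca_scaled(m)
        proj = project(space, m)
        for _, row in proj.iterrows():
            pc1, pc2 = row["PC1"], row["PC2"]
            expect = {(True, True): "I", (False, True): "II",
                      (False, False): "III", (True, False): "IV"}[
                          (pc1 >= 0, pc2 >= 0)]
            assert row["quadrant"] == expect

    def test_trait_mismatch_rejected(self):
        m = entity_matrix([[1.0, 2.0], [2.0, 1.0], [0.0, 3.0]])
        space = pca_scaled(m)
        with pytest.raises(ValueError, match="mismatch"):
            project(space, m.rename(columns={"t0": "other"}))


class TestSlopeScreen:
    def _table(self, groups):
        rows = []
        for geno, pts in groups.items():
            for i, (x, y) in enumerate(pts):
                rows.append((2020, 1, "optimal", "split", "early", geno, "GCD", x))
                rows.append((2020, 1, "optimal", "split", "early", geno,
                             "WSC_conc_87_straw", y))
        # pivot key needs distinct management cells per point
        df = make_table(rows)
        reps = []
        for geno, pts in groups.items():
            for i in range(len(pts)):
                reps.extend([i, i])
        df["block"] = reps  # distinct key per point
        return df

    def test_noiseless_line_recovered(self):
        xs = np.arange(8, dtype=float)
        tbl = self._table({"Capone": [(x, 2 * x + 1) for x in xs]})
        res = slope_screen(tbl, "GCD", "WSC_conc_87_straw", ["genotype"])
        assert len(res) == 1
        assert res["slope"].iloc[0] == pytest.approx(2.0)
        assert res["intercept"].iloc[0] == pytest.approx(1.0)
        assert bool(res["significant"].iloc[0])

    def test_small_group_skipped_with_warning(self):
        tbl = self._table({"Capone": [(0.0, 1.0), (1.0, 2.0)]})
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = slope_screen(tbl, "GCD", "WSC_conc_87_straw", ["genotype"])
        assert res.empty

    def test_degenerate_x_skipped(self):
        tbl = self._table({"Capone": [(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)]})
        with pytest.warns(UserWarning, match="degenerate"):
            res = slope_screen(tbl, "GCD", "WSC_conc_87_straw", ["genotype"])
        assert res.empty

    def test_null_flag_rate_near_alpha(self):
        """Independent x, y: the 5% slope test flags ~5% of groups."""
        rng = np.random.default_rng(11)
        groups = {
            f"g{i}": list(zip(rng.normal(size=8), rng.normal(size=8)))
            for i in range(500)
        }
        tbl = self._table(groups)
        res = slope_screen(tbl, "GCD", "WSC_conc_87_straw", ["genotype"])
        rate = res["significant"].mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_closed_form_least_squares_agreement(self):
        rng = np.random.default_rng(12)
        pts = [(x, 0.5 * x + rng.normal()) for x in np.linspace(0, 10, 8)]
        tbl = self._table({"Capone": pts})
        res = slope_screen(tbl, "GCD", "WSC_conc_87_straw", ["genotype"])
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res["slope"].iloc[0] == pytest.approx(beta, rel=1e-10)
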