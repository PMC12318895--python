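import numpy as np
import pandas as pd
import pytest

from gcspatial.celltable import CellTable
from gcspatial.clustering import (batch_cluster, downsample_concatenate,
                                  metacluster, prevalence_matrix, train_som,
                                  zscore_normalize)
from gcspatial.errors import ConfigurationError, InsufficientDataError


def _table(tissue_id, values, markers=("M1", "M2")):
    n = len(values)
    df = pd.DataFrame({
        "cell_id": [f"{tissue_id}-{i}" for i in range(n)],
        "tissue_id": tissue_id,
        "x_um": np.arange(n, dtype=float), "y_um": np.zeros(n),
        "volume_um3": 300.0, "sphericity": 0.8,
    })
    for j, m in enumerate(markers):
        df[m] = np.asarray(values)[:, j] if np.ndim(values) == 2 else np.asarray(values)
    return CellTable(df, list(markers))


class TestZScore:
    def test_known_column(self):
        t = _table("T", np.column_stack([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        out = zscore_normalize(t)
        np.testing.assert_allclose(out.df["M1"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_marker_warns_and_zeroes(self):
        t = _table("T", np.column_stack([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_normalize(t)
        assert (out.df["M1"] == 0).all()

    def test_group_mean_zero_sd_one(self, basic_tissue):
        table, _ = basic_tissue
        out = zscore_normalize(table, per_tissue=True)
        for m in table.markers:
            assert abs(out.df[m].mean()) < 1e-9
            assert out.df[m].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, basic_tissue):
        table, _ = basic_tissue
        once = zscore_normalize(table)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(twice.df[table.markers].to_numpy(),
                                   once.df[table.markers].to_numpy(), atol=1e-9)

    def test_coordinates_untouched(self, basic_tissue):
        table, _ = basic_tissue
        out = zscore_normalize(table)
        for col in ["x_um", "y_um", "volume_um3", "sphericity"]:
            np.testing.assert_array_equal(out.df[col], table.df[col])

    def test_tiny_group_rejected(self):
        t = _table("T", np.array([[1.0, 2.0]]))
        with pytest.raises(InsufficientDataError, match="T"):
            zscore_normalize(t)


class TestDownsample:
    def _tissues(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        return [_table(f"T{i}", rng.normal(size=(n, 2))) for i, n in enumerate(sizes)]

    def test_equal_counts_concatenated(self):
        out = downsample_concatenate(self._tissues([5000, 5000, 5000, 5000]), 2200, seed=1)
        counts = out.df.tissue_id.value_counts()
        assert (counts == 2200).all() and len(out) == 8800

    def test_small_tissue_excluded(self):
        out = downsample_concatenate(self._tissues([3000, 1500]), 2200, seed=1)
        assert set(out.df.tissue_id) == {"T0"}

    def test_all_below_n_is_error(self):
        with pytest.raises(InsufficientDataError):
            downsample_concatenate(self._tissues([10, 20]), 2200)

    def test_deterministic_and_without_replacement(self):
        tissues = self._tissues([3000])
        a = downsample_concatenate(tissues, 500, seed=9)
        b = downsample_concatenate(tissues, 500, seed=9)
        assert a.df.cell_id.tolist() == b.df.cell_id.tolist()
        assert a.df.cell_id.is_unique


class TestSOM:
    def test_constant_data_fixed_point(self):
        X = np.tile([1.0, -2.0, 3.0], (150, 1))
        model = train_som(X, grid=(3, 3), epochs=5)
        np.testing.assert_allclose(model.codebook, np.tile([1.0, -2.0, 3.0], (9, 1)),
                                   atol=1e-9)
        assert model.quantisation_errors[-1] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError, match="smaller grid"):
            train_som(np.zeros((50, 3)), grid=(10, 10))

    def test_deterministic(self, rng):
        X = rng.normal(size=(400, 5))
        a = train_som(X, grid=(4, 4), seed=3)
        b = train_som(X, grid=(4, 4), seed=3)
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_blob_recovery_and_quantisation_error_decreases(self, rng):
        # 8 isotropic blobs, 14 markers, separation >= 6 sigma
        centres = rng.normal(scale=10.0, size=(8, 14))
        from scipy.spatial.distance import pdist
        while pdist(centres).min() < 6.0:
            centres = rng.normal(scale=10.0, size=(8, 14))
        lab = rng.integers(0, 8, 2000)
        X = centres[lab] + rng.normal(size=(2000, 14))
        model = train_som(X, grid=(10, 10), epochs=20, seed=0)
        nodes = model.predict_nodes(X)
        node_centre = np.argmin(
            ((model.codebook[:, None, :] - centres[None, :, :]) ** 2).sum(-1), axis=1)
        assert (node_centre[nodes] == lab).mean() >= 0.99
        q = model.quantisation_errors
        assert all(q[i + 1] <= q[i] + 1e-9 for i in range(len(q) - 6, len(q) - 1))


class TestMetacluster:
    def _blob_model(self, rng, k=8):
        centres = rng.normal(scale=10.0, size=(k, 14))
        lab = rng.integers(0, k, 2000)
        X = centres[lab] + rng.normal(size=(2000, 14))
        return train_som(X, grid=(10, 10), seed=0), X, lab

    def test_k_one_and_k_nodes(self, rng):
        model, _, _ = self._blob_model(rng)
        m1 = metacluster(model, 1)
        assert set(m1.metacluster_of_node) == {0}
        mN = metacluster(model, model.n_nodes)
        assert len(set(mN.metacluster_of_node)) == model.n_nodes

    def test_k_above_node_count_rejected(self, rng):
        model, _, _ = self._blob_model(rng)
        with pytest.raises(ConfigurationError):
            metacluster(model, 101)

    def test_blob_ari(self, rng):
        from sklearn.metrics import adjusted_rand_score

        model, X, lab = self._blob_model(rng)
        model = metacluster(model, 8)
        pred = model.predict_metaclusters(X)
        assert adjusted_rand_score(lab, pred) >= 0.9

    def test_p_numbers_ordered_by_prevalence(self, rng):
        model, X, _ = self._blob_model(rng)
        model = metacluster(model, 8)
        pred = model.predict_metaclusters(X)
        counts = np.bincount(pred, minlength=8)
        assert (np.diff(counts) <= 0).all()


class TestPrevalence:
    def test_rows_sum_to_downsampled_n(self):
        labels = np.array([0, 1, 1, 0, 2, 2, 2, 1])
        tissues = ["A"] * 4 + ["B"] * 4
        mat = prevalence_matrix(labels, tissues, k=3)
        assert mat.sum(axis=1).tolist() == [4, 4]

    def test_log1p_transform_is_elementwise_ln_1_plus_count(self):
        out = prevalence_matrix(np.array([0, 0, 1]), ["A", "A", "A"],
                                transform="log1p", k=2)
        np.testing.assert_allclose(out.to_numpy(), [[np.log1p(2), np.log1p(1)]])

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            prevalence_matrix(np.array([0]), ["A"], transform="sqrt", k=1)


class TestEndToEnd:
    def test_planted_cluster_recovery_through_pipeline(self):
        from sklearn.metrics import adjusted_rand_score

        from gcspatial.scenarios import PANEL_MARKERS, cohort_specs
        from gcspatial.synthetic import simulate_tissue

        pairs = [simulate_tissue(s) for s in cohort_specs(4, seed=21)]
        res = batch_cluster([p[0] for p in pairs], PANEL_MARKERS,
                            n_downsample=1500, seed=0)
        truth = {}
        for _, gt in pairs:
            truth.update(dict(zip(gt.df.cell_id, gt.df.population)))
        lab = [truth[c] for c in res.table.df.cell_id]
        assert adjusted_rand_score(lab, res.cell_metaclusters) >= 0.9
        assert res.prevalence.sum(axis=1).tolist() == [1500] * 4
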