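import numpy as np
import pandas as pd
import pytest

from gcspatial.celltable import CellTable
from gcspatial.config import ArtefactFilterParams
from gcspatial.errors import ConfigurationError, InsufficientDataError
from gcspatial.gating import (GateTree, apply_gates, count_populations,
                              derive_threshold, derive_thresholds,
                              filter_artefacts, filter_geometry)


def _table(markers, intensities, medians=None, **geom):
    n = len(next(iter(intensities.values())))
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "tissue_id": geom.get("tissue_id", ["T"] * n),
        "x_um": np.arange(n, dtype=float),
        "y_um": np.zeros(n),
        "volume_um3": geom.get("volume", np.full(n, 300.0)),
        "sphericity": geom.get("sphericity", np.full(n, 0.8)),
    })
    for m in markers:
        df[m] = intensities[m]
        if medians is not None:
            df[f"{m}_median"] = medians[m]
    return CellTable(df, list(markers))


class TestArtefactFilter:
    MARKERS = [f"M{i}" for i in range(6)]

    def test_uniform_cell_removed_diverse_cell_kept(self):
        # cell 0: mean == median in all 6 channels; cell 1: mean = 1.8 x median
        inten = {m: [50.0, 50.0] for m in self.MARKERS}
        med = {m: [50.0, 50.0 / 1.8] for m in self.MARKERS}
        t = _table(self.MARKERS, inten, med)
        kept, removed = filter_artefacts(t, ArtefactFilterParams(epsilon=0.05, m_channels=4))
        assert list(removed.df.cell_id) == ["c0"]
        assert list(kept.df.cell_id) == ["c1"]

    def test_low_intensity_channels_do_not_count(self):
        # uniform staining but below min_level -> kept
        inten = {m: [5.0] for m in self.MARKERS}
        med = {m: [5.0] for m in self.MARKERS}
        t = _table(self.MARKERS, inten, med)
        kept, removed = filter_artefacts(
            t, ArtefactFilterParams(epsilon=0.05, m_channels=4, min_level=10.0))
        assert removed.n_cells == 0

    def test_missing_median_columns_is_configuration_error(self):
        t = _table(self.MARKERS, {m: [50.0] for m in self.MARKERS})
        with pytest.raises(ConfigurationError, match="median"):
            filter_artefacts(t, ArtefactFilterParams())

    def test_recall_precision_on_planted_artefacts(self):
        from gcspatial.scenarios import basic_tissue_spec
        from gcspatial.synthetic import simulate_tissue

        table, gt = simulate_tissue(basic_tissue_spec(seed=4, artefact_fraction=0.1,
                                                      cells_scale=2.0))
        kept, removed = filter_artefacts(table, ArtefactFilterParams(epsilon=0.05, m_channels=4))
        truth = gt.df.set_index("cell_id")["is_artefact"]
        flagged = truth.reindex(removed.df.cell_id)
        precision = flagged.mean()
        recall = flagged.sum() / truth.sum()
        assert precision >= 0.95 and recall >= 0.95


class TestGeometryFilter:
    def test_bounds_rule(self):
        t = _table(["M"], {"M": [1.0, 1.0, 1.0]},
                   volume=np.array([5.0, 300.0, 300.0]),
                   sphericity=np.array([0.8, 0.8, 0.1]))
        kept, removed = filter_geometry(t, 50.0, 4000.0, 0.3)
        assert set(removed.df.cell_id) == {"c0", "c2"}

    def test_all_pass_is_identity_partition(self):
        t = _table(["M"], {"M": [1.0, 2.0]})
        kept, removed = filter_geometry(t, 50.0, 4000.0, 0.3)
        assert removed.n_cells == 0 and kept.n_cells == 2

    def test_planted_debris_exactly_removed(self):
        from gcspatial.scenarios import basic_tissue_spec
        from gcspatial.synthetic import simulate_tissue

        table, gt = simulate_tissue(basic_tissue_spec(seed=6, debris_fraction=0.1))
        kept, removed = filter_geometry(table, 50.0, 4000.0, 0.3)
        truth = gt.df.set_index("cell_id")["is_debris"]
        assert truth.reindex(removed.df.cell_id).all()
        assert truth.sum() == removed.n_cells

    def test_filters_are_idempotent(self):
        t = _table(["M"], {"M": np.ones(10)}, volume=np.linspace(10, 5000, 10))
        kept, _ = filter_geometry(t, 50.0, 4000.0, 0.3)
        kept2, removed2 = filter_geometry(kept, 50.0, 4000.0, 0.3)
        assert removed2.n_cells == 0


class TestDeriveThreshold:
    def test_separates_known_lognormal_mixture(self, rng):
        lo = np.exp(rng.normal(1.0, 0.3, 500))
        hi = np.exp(rng.normal(4.0, 0.3, 500))
        values = np.concatenate([lo, hi])
        thr = derive_threshold(values, seed=0)
        assert np.exp(1) < thr.value < np.exp(4)
        miscls = ((values >= thr.value) != np.r_[np.zeros(500, bool), np.ones(500, bool)]).mean()
        assert miscls < 0.02
        assert thr.reliable

    def test_valley_method_agrees_roughly(self, rng):
        values = np.concatenate([np.exp(rng.normal(1.0, 0.3, 500)),
                                 np.exp(rng.normal(4.0, 0.3, 500))])
        t_mix = derive_threshold(values, "mixture").value
        t_val = derive_threshold(values, "valley").value
        assert np.exp(1) < t_val < np.exp(4)
        assert abs(np.log(t_val) - np.log(t_mix)) < 1.0

    def test_constant_input_flagged_unreliable(self):
        with pytest.warns(UserWarning, match="unreliable"):
            thr = derive_threshold(np.full(100, 7.0))
        assert not thr.reliable

    def test_unimodal_input_flagged_unreliable(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            thr = derive_threshold(np.exp(rng.normal(2.0, 0.3, 400)), seed=0)
        assert not thr.reliable

    def test_permutation_invariant(self, rng):
        values = np.concatenate([np.exp(rng.normal(1.0, 0.3, 200)),
                                 np.exp(rng.normal(4.0, 0.3, 200))])
        a = derive_threshold(values, seed=0).value
        b = derive_threshold(rng.permutation(values), seed=0).value
        assert a == pytest.approx(b, rel=1e-6)

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_threshold(np.ones(10))


class TestApplyGates:
    TREE = [
        {"marker": "CD3", "direction": "hi", "threshold": 10.0, "population": "CD3hi",
         "children": [{"marker": "PD1", "direction": "hi", "threshold": 10.0,
                       "population": "TFH"}]},
    ]

    def test_hierarchical_labels(self):
        t = _table(["CD3", "PD1"], {"CD3": [20.0, 20.0, 5.0], "PD1": [20.0, 5.0, 20.0]})
        out = apply_gates(t, GateTree.from_dict(self.TREE))
        assert out.has_label("CD3hi").tolist() == [True, True, False]
        assert out.has_label("TFH").tolist() == [True, False, False]

    def test_child_label_implies_parent_label(self, basic_tissue):
        from gcspatial.scenarios import GATE_MARKERS, default_gate_tree

        table, _ = basic_tissue
        tree = default_gate_tree()
        tree.fill_thresholds(derive_thresholds(table, GATE_MARKERS, seed=0))
        out = apply_gates(table, tree)
        tfh = out.has_label("TFH")
        assert (~tfh | out.has_label("CD3hi")).all()

    def test_threshold_at_boundary_is_closed_for_hi(self):
        t = _table(["CD3"], {"CD3": [10.0]})
        out = apply_gates(t, GateTree.from_dict(
            [{"marker": "CD3", "direction": "hi", "threshold": 10.0, "population": "X"}]))
        assert out.has_label("X").all()

    def test_unknown_marker_raises(self):
        t = _table(["CD3"], {"CD3": [10.0]})
        with pytest.raises(ConfigurationError, match="CD99"):
            apply_gates(t, GateTree.from_dict(
                [{"marker": "CD99", "threshold": 1.0, "population": "X"}]))

    def test_monotone_in_threshold(self, basic_tissue):
        table, _ = basic_tissue
        base = [{"marker": "CD20", "direction": "hi", "threshold": 5.0, "population": "B"}]
        n_low = apply_gates(table, GateTree.from_dict(base)).has_label("B").sum()
        base[0]["threshold"] = 8.0
        n_high = apply_gates(table, GateTree.from_dict(base)).has_label("B").sum()
        assert n_high <= n_low

    def test_manual_threshold_wins_over_derived(self):
        tree = GateTree.from_dict(
            [{"marker": "CD3", "direction": "hi", "threshold": 123.0, "population": "X"}])
        tree.fill_thresholds({"CD3": 5.0})
        assert tree.roots[0].threshold == 123.0
        tree.fill_thresholds({"CD3": 5.0}, overwrite=True)
        assert tree.roots[0].threshold == 5.0


class TestCountPopulations:
    def _labelled(self):
        t = _table(["M"], {"M": np.ones(5)})
        t.add_labels(np.array([1, 1, 1, 0, 0], bool), "A")
        t.add_labels(np.array([0, 0, 1, 1, 0], bool), "B")
        return t

    def test_combination_counts_by_hand(self):
        t = self._labelled()
        out = count_populations(t, combos=["A+B+", "A+B-"])
        counts = dict(zip(out.population, out["count"]))
        assert counts == {"A+B+": 1, "A+B-": 2}

    def test_partitioning_combos_sum_to_100pct_of_parent(self):
        t = self._labelled()
        out = count_populations(t, combos=["A+B+", "A+B-"], parent="A")
        assert out.frequency_pct.sum() == pytest.approx(100.0)

    def test_unknown_label_lists_known(self):
        t = self._labelled()
        with pytest.raises(ValueError, match="known labels"):
            count_populations(t, combos=["A+C+"])

    def test_empty_table_all_zero(self):
        t = _table(["M"], {"M": np.array([])})
        out = count_populations(t, populations=["A"])
        assert (out["count"] == 0).all()
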