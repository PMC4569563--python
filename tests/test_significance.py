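"""The two-rule differential-expression screen and leaf exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seasonet.model import ConditionKey
from seasonet.significance import (
    compute_stats,
    root_specific,
    screen,
    select_significant,
)

from conftest import make_matrix
from oracles import select_significant_oracle


def random_series(rng, n_genes, n_timepoints):
    """Mix of flat, high-mean and high-variance genes, as the screen expects."""
    out = {}
    for i in range(n_genes):
        kind = rng.integers(0, 3)
        if kind == 0:
            out[f"g{i}"] = [float(rng.uniform(0, 2))] * n_timepoints
        elif kind == 1:
            out[f"g{i}"] = list(rng.uniform(0, 10, n_timepoints))
        else:
            out[f"g{i}"] = list(rng.uniform(0, 1, n_timepoints))
    return out


class TestComputeStats:
    def test_hand_worked_statistics(self):
        stats = compute_stats(make_matrix({"A": [2, 4, 6], "B": [1, 1, 1]}))
        assert stats.mean_t["A"] == pytest.approx(4.0)
        assert stats.mean_t["B"] == pytest.approx(1.0)
        assert stats.sd_t["A"] == pytest.approx(2.0)
        assert stats.sd_t["B"] == pytest.approx(0.0)
        assert stats.mu_of_means == pytest.approx(2.5)
        assert stats.sd_of_means == pytest.approx(2.1213, abs=1e-4)
        assert stats.t1_threshold == pytest.approx(4.6213, abs=1e-4)

    def test_identical_series_degenerate_thresholds(self):
        stats = compute_stats(make_matrix({"A": [1, 2, 3], "B": [1, 2, 3], "C": [1, 2, 3]}))
        assert stats.sd_of_means == pytest.approx(0.0)
        assert stats.sd_of_sds == pytest.approx(0.0)
        assert stats.t1_threshold == pytest.approx(stats.mu_of_means)
        assert stats.t2_threshold == pytest.approx(stats.mu_of_sds)

    def test_too_few_timepoints_or_genes(self):
        with pytest.raises(ValueError, match="timepoints"):
            compute_stats(make_matrix({"A": [1], "B": [2]}))
        with pytest.raises(ValueError, match="genes"):
            compute_stats(make_matrix({"A": [1, 2, 3]}))

    def test_population_sd_mode(self):
        stats = compute_stats(make_matrix({"A": [2, 4, 6], "B": [1, 1, 1]}), sd_mode="population")
        assert stats.sd_t["A"] == pytest.approx(np.sqrt(8 / 3))
        with pytest.raises(ValueError, match="sd_mode"):
            compute_stats(make_matrix({"A": [1, 2], "B": [1, 2]}), sd_mode="bogus")


class TestSelectSignificant:
    def test_selection_by_high_mean(self):
        """One constant high gene among constant low genes: picked by the
        mean rule; the flat-gene guard blocks the variability rule."""
        sel = screen(make_matrix({"A": [10, 10, 10], "B": [1, 1, 1], "C": [1, 1, 1]}))
        assert sel.genes == {"A"}
        assert sel.basis["A"] == "mean"

    def test_selection_by_high_variability(self):
        sel = screen(make_matrix({"A": [0, 10, 0], "B": [5, 5, 5], "C": [5, 5, 5]}))
        assert sel.genes == {"A"}
        assert sel.basis["A"] == "variability"

    def test_two_distinct_constant_genes_select_nothing(self):
        """With sample sd, mean + sd = mean + |a-b|/sqrt(2) exceeds both
        values, so neither of two distinct flat genes can pass."""
        sel = screen(make_matrix({"A": [3, 3, 3], "B": [7, 7, 7]}))
        assert sel.genes == set()

    def test_flat_matrix_never_selected_for_variability(self):
        """All-identical flat matrix: the inclusive mean rule degenerates to
        mean >= mean (all genes pass), but the sd>0 guard keeps the
        variability rule from firing for constant series."""
        sel = screen(make_matrix({"A": [2, 2, 2], "B": [2, 2, 2], "C": [2, 2, 2]}))
        assert all(b == "mean" for b in sel.basis.values())

    def test_matches_independent_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            series = random_series(rng, int(rng.integers(3, 11)), int(rng.integers(3, 11)))
            assert screen(make_matrix(series)).genes == select_significant_oracle(series)

    def test_population_mode_matches_oracle(self, rng):
        for _ in range(50):
            series = random_series(rng, 5, 6)
            got = screen(make_matrix(series), sd_mode="population").genes
            assert got == select_significant_oracle(series, sample_sd=False)


class TestInvariances:
    @given(c=st.floats(-0.0, 50), k=st.floats(0.1, 20), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, c, k, seed):
        """Selection is unchanged under x -> k*x + c (k > 0): both sides of
        the mean rule shift and scale together, the variability rule scales."""
        rng = np.random.default_rng(seed)
        series = random_series(rng, int(rng.integers(3, 8)), int(rng.integers(3, 8)))
        base = screen(make_matrix(series)).genes
        mapped = {g: [k * v + c for v in xs] for g, xs in series.items()}
        assert screen(make_matrix(mapped)).genes == base

    def test_gene_order_permutation_invariance(self, rng):
        series = random_series(rng, 8, 6)
        base = screen(make_matrix(series)).genes
        order = list(series)
        rng.shuffle(order)
        assert screen(make_matrix({g: series[g] for g in order})).genes == base

    def test_timepoint_relabeling_invariance(self, rng):
        """Reordering timepoints identically for all genes changes nothing:
        both rules are symmetric in time."""
        series = random_series(rng, 6, 7)
        base = screen(make_matrix(series)).genes
        perm = rng.permutation(7)
        shuffled = {g: [xs[p] for p in perm] for g, xs in series.items()}
        assert screen(make_matrix(shuffled)).genes == base

    def test_raising_a_gene_eventually_selects_it(self):
        series = {"A": [1.0, 1.2, 0.9], "B": [1.1, 1.0, 1.2], "C": [0.9, 1.0, 1.1]}
        lifted = dict(series, A=[v + 10 for v in series["A"]])
        sel = screen(make_matrix(lifted))
        assert "A" in sel.genes
        assert sel.basis["A"] in ("mean", "both")  # the mean rule fired


class TestRootSpecific:
    def _sets(self, mapping):
        return {
            cond: screen(make_matrix(series, cond)) for cond, series in mapping.items()
        }

    def test_leaf_exclusion_is_set_difference(self):
        c_wet = ConditionKey("cortex", "wet")
        l_wet = ConditionKey("leaf", "wet")
        root = self._sets({c_wet: {"A": [9, 9, 9], "B": [0, 9, 0], "C": [1, 1, 1], "D": [1, 1, 1]}})
        # B significant in leaf too -> excluded from the root-specific set
        leaf = self._sets({l_wet: {"A": [1, 1, 1], "B": [0, 9, 0], "C": [1, 1, 1], "D": [1, 1, 1]}})
        out = root_specific(root, leaf)
        assert out[c_wet].genes == root[c_wet].genes - {"B"}
        assert all(g in root[c_wet].basis for g in out[c_wet].genes)

    def test_empty_leaf_set_changes_nothing(self):
        c_dry = ConditionKey("cortex", "dry")
        root = self._sets({c_dry: {"A": [9, 9, 9], "B": [1, 1, 1], "C": [1, 1, 1]}})
        out = root_specific(root, {})
        assert out[c_dry].genes == root[c_dry].genes

    def test_season_matched_vs_global_mode(self):
        c_wet, c_dry = ConditionKey("cortex", "wet"), ConditionKey("cortex", "dry")
        l_wet, l_dry = ConditionKey("leaf", "wet"), ConditionKey("leaf", "dry")
        root = self._sets({
            c_wet: {"A": [9, 9, 9], "B": [0, 9, 0], "C": [1, 1, 1], "D": [1, 1, 1]},
            c_dry: {"A": [9, 9, 9], "B": [0, 9, 0], "C": [1, 1, 1], "D": [1, 1, 1]},
        })
        leaf = self._sets({
            l_wet: {"A": [1, 1, 1], "B": [0, 9, 0], "C": [1, 1, 1], "D": [1, 1, 1]},
            l_dry: {"A": [0, 9, 0], "B": [1, 1, 1], "C": [1, 1, 1], "D": [1, 1, 1]},
        })
        season = root_specific(root, leaf, mode="season")
        # wet leaf knocks out B in wet root only; dry leaf knocks out A in dry root only
        assert "B" not in season[c_wet].genes and "A" in season[c_wet].genes
        assert "A" not in season[c_dry].genes and "B" in season[c_dry].genes
        global_ = root_specific(root, leaf, mode="global")
        assert "A" not in global_[c_wet].genes and "B" not in global_[c_wet].genes

    def test_synthetic_decoys_never_root_specific(self, default_dataset):
        screens = {c: screen(m) for c, m in default_dataset.matrices.items()}
        out = root_specific(
            {c: s for c, s in screens.items() if c.is_root},
            {c: s for c, s in screens.items() if not c.is_root},
        )
        for sset in out.values():
            assert sset.genes.isdisjoint(default_dataset.truth.leaf_decoys)
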