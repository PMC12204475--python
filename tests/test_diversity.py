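"""Diversity indices, Hill-number rarefaction, bootstraps, STARTRAC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airrtoolkit.diversity import (
    bootstrapped_diversity,
    diversity_indices,
    rarefaction_curve,
    startrac_indices,
)
from airrtoolkit.errors import (
    GridOutOfRange,
    GroupTooSmall,
    InvalidCounts,
    InvalidOrder,
    MissingLabel,
)

count_vectors = st.lists(
    st.integers(min_value=1, max_value=40), min_size=1, max_size=40
)


class TestClosedForms:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (
                [1, 1, 1, 1],
                {"shannon": np.log(4), "inv_simpson": 4.0, "norm_entropy": 1.0,
                 "gini_simpson": 0.75, "chao1": 10.0},
            ),
            (
                [2, 1, 1],
                {"shannon": 1.0397207708399179, "inv_simpson": 8 / 3,
                 "chao1": 3.5},
            ),
            ([5], {"shannon": 0.0, "inv_simpson": 1.0, "norm_entropy": 0.0}),
        ],
    )
    def test_hand_values(self, counts, expected):
        got = diversity_indices(counts)
        for metric, value in expected.items():
            assert got[metric] == pytest.approx(value, abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(InvalidCounts):
            diversity_indices([2, 0, 1])
        with pytest.raises(InvalidCounts):
            diversity_indices([])

    @settings(max_examples=50, deadline=None)
    @given(count_vectors)
    def test_chao1_lower_bound(self, counts):
        x = np.asarray(counts)
        got = diversity_indices(x)
        assert got["chao1"] >= x.size - 1e-12
        if np.sum(x == 1) <= 1:
            assert got["chao1"] == pytest.approx(x.size)


class TestHillConsistency:
    def test_hill_orders_match_indices_at_observed_depth(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            x = rng.integers(1, 40, size=rng.integers(2, 50))
            n = int(x.sum())
            idx = diversity_indices(x)
            q1 = rarefaction_curve(x, q=1, m_grid=[n], n_boot=0)["estimate"].iloc[0]
            q2 = rarefaction_curve(x, q=2, m_grid=[n], n_boot=0)["estimate"].iloc[0]
            assert abs(np.exp(idx["shannon"]) - q1) < 1e-9
            assert abs(idx["inv_simpson"] - q2) < 1e-9

    def test_q0_at_full_depth_is_richness(self):
        x = [4, 3, 2, 1]
        curve = rarefaction_curve(x, q=0, m_grid=[10], n_boot=0)
        assert curve["estimate"].iloc[0] == pytest.approx(4.0)
        assert curve["regime"].iloc[0] == "observed"


class TestRarefactionInterpolation:
    def test_m_equals_one(self):
        for q in (0, 1, 2):
            curve = rarefaction_curve([7, 3, 2], q=q, m_grid=[1], n_boot=0)
            assert curve["estimate"].iloc[0] == pytest.approx(1.0)

    def test_hypergeometric_hand_value(self):
        # [2,1,1] at m=2: 3 - [C(2,2)+C(3,2)+C(3,2)]/C(4,2) = 11/6
        curve = rarefaction_curve([2, 1, 1], q=0, m_grid=[2], n_boot=0)
        assert curve["estimate"].iloc[0] == pytest.approx(11 / 6, abs=1e-12)

    def test_q0_matches_monte_carlo_subsampling(self):
        """Exact interpolation vs 10,000-draw subsampling, 3 MC SEs."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            x = rng.integers(1, 15, size=rng.integers(3, 20))
            n = int(x.sum())
            m = int(rng.integers(2, n))
            est = rarefaction_curve(x, q=0, m_grid=[m], n_boot=0)["estimate"].iloc[0]
            labels = np.repeat(np.arange(x.size), x)
            B = 10_000
            keys = rng.random((B, n))
            idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
            sub = np.sort(labels[idx], axis=1)
            richness = 1 + (np.diff(sub, axis=1) != 0).sum(axis=1)
            se = richness.std(ddof=1) / np.sqrt(B)
            # 1/B floor: events rarer than one draw in B are invisible to MC
            assert abs(richness.mean() - est) <= 3 * se + 1.0 / B

    def test_interpolated_richness_nondecreasing(self):
        x = [9, 4, 4, 2, 1, 1]
        n = int(np.sum(x))
        curve = rarefaction_curve(x, q=0, m_grid=list(range(1, n + 1)), n_boot=0)
        assert (np.diff(curve["estimate"]) >= -1e-12).all()

    def test_extrapolation_regime_and_monotonicity(self):
        x = [5, 3, 1, 1]
        curve = rarefaction_curve(x, q=0, m_grid=[10, 15, 20], n_boot=0)
        assert list(curve["regime"]) == ["observed", "extrapolated",
                                         "extrapolated"]
        assert (np.diff(curve["estimate"]) >= -1e-12).all()

    def test_invalid_order_and_grid(self):
        with pytest.raises(InvalidOrder):
            rarefaction_curve([2, 1], q=3)
        with pytest.raises(GridOutOfRange):
            rarefaction_curve([2, 1], q=0, m_grid=[100], endpoint=6)

    def test_bootstrap_ci_seeded_and_brackets_estimate(self):
        x = np.r_[np.full(5, 10), np.full(20, 2), np.ones(30)]
        a = rarefaction_curve(x, q=1, m_grid=[20, 50], n_boot=30, seed=5)
        b = rarefaction_curve(x, q=1, m_grid=[20, 50], n_boot=30, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a["lower"] <= a["upper"]).all()


class TestBootstrappedDiversity:
    def test_full_size_downsample_reproduces_point_estimate(self):
        tab = pd.DataFrame({"g1": [5, 3, 2], "g2": [4, 4, 2]},
                           index=["a", "b", "c"])
        out = bootstrapped_diversity(tab, n_boot=20, seed=0)
        for _, row in out.iterrows():
            assert row["boot_mean"] == pytest.approx(row["point"], abs=1e-12)
            assert row["boot_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_forced_outcome_uniform_singletons(self):
        tab = pd.DataFrame(
            {"g": np.ones(100, dtype=int), "h": [1] * 50 + [0] * 50},
            index=[f"c{i}" for i in range(100)],
        )
        out = bootstrapped_diversity(tab, metrics=("inv_simpson",),
                                     n_boot=10, seed=1)
        g = out[out["group"] == "g"].iloc[0]
        assert g["n_downsample"] == 50
        assert g["boot_mean"] == pytest.approx(50.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        tab = pd.DataFrame({"g1": rng.integers(1, 9, 30),
                            "g2": rng.integers(1, 9, 30)},
                           index=[f"c{i}" for i in range(30)])
        a = bootstrapped_diversity(tab, n_boot=25, seed=123)
        b = bootstrapped_diversity(tab, n_boot=25, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_group_too_small(self):
        tab = pd.DataFrame({"g1": [50], "g2": [2]}, index=["a"])
        with pytest.raises(GroupTooSmall):
            bootstrapped_diversity(tab, downsample_to=10)


class TestStartrac:
    def test_uniform_clone_sizes_no_expansion(self):
        cells = pd.DataFrame({
            "clone": ["a", "a", "b", "b"],
            "cluster": ["X"] * 4,
            "tissue": ["T1"] * 4,
        })
        out = startrac_indices(cells)
        assert out["expa"].iloc[0] == pytest.approx(0.0)

    def test_hand_value_3_1(self):
        cells = pd.DataFrame({
            "clone": ["a", "a", "a", "b"],
            "cluster": ["X"] * 4,
            "tissue": ["T1"] * 4,
        })
        out = startrac_indices(cells)
        assert out["expa"].iloc[0] == pytest.approx(0.1887, abs=2e-4)

    def test_single_clone_cluster_expa_missing(self):
        cells = pd.DataFrame({
            "clone": ["a", "a"], "cluster": ["X", "X"], "tissue": ["T1", "T1"],
        })
        out = startrac_indices(cells)
        assert np.isnan(out["expa"].iloc[0])

    def test_pure_clones_zero_migration_transition(self):
        cells = pd.DataFrame({
            "clone": ["a", "a", "b"],
            "cluster": ["X", "X", "Y"],
            "tissue": ["T1", "T1", "T2"],
        })
        out = startrac_indices(cells)
        assert (out["migr"] == 0).all() and (out["tran"] == 0).all()

    def test_split_clone_positive_indices(self):
        cells = pd.DataFrame({
            "clone": ["a"] * 4,
            "cluster": ["X", "X", "Y", "Y"],
            "tissue": ["T1", "T2", "T1", "T2"],
        })
        out = startrac_indices(cells)
        assert out["migr"].tolist() == pytest.approx([np.log(2)] * 2)
        assert out["tran"].tolist() == pytest.approx([np.log(2)] * 2)

    def test_expa_invariant_to_clone_relabeling(self):
        cells = pd.DataFrame({
            "clone": ["a", "a", "a", "b", "c"],
            "cluster": ["X"] * 5,
            "tissue": ["T1"] * 5,
        })
        relabeled = cells.assign(clone=cells["clone"].map(
            {"a": "z9", "b": "q1", "c": "m5"}
        ))
        assert startrac_indices(cells)["expa"].iloc[0] == pytest.approx(
            startrac_indices(relabeled)["expa"].iloc[0]
        )

    def test_missing_label_rejected(self):
        cells = pd.DataFrame({
            "clone": ["a", None], "cluster": ["X", "X"], "tissue": ["T1", "T1"],
        })
        with pytest.raises(MissingLabel):
            startrac_indices(cells)
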