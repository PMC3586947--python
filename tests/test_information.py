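import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet import (
    DegenerateInputError,
    ValidationError,
    default_n_bins,
    entropy,
    equal_width_discretize,
    joint_entropy,
    lrt_statistic,
    mi_matrix,
    mutual_information,
)
from coexnet.information import contingency_table

from oracles import entropy_oracle, mi_plugin_oracle


class TestDefaultBins:
    @pytest.mark.parametrize("m,expected", [(100, 10), (1000, 32), (4, 2), (9, 3)])
    def test_rounded_sqrt(self, m, expected):
        assert default_n_bins(m) == expected

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            default_n_bins(3)


class TestDiscretize:
    def test_forced_assignment(self):
        assert equal_width_discretize([0, 1, 2, 3], 2).bins.tolist() == [1, 1, 2, 2]

    def test_endpoints_map_to_extreme_bins(self):
        assert equal_width_discretize([0, 3], 3).bins.tolist() == [1, 3]

    def test_matches_interval_membership_oracle(self, rng):
        x = rng.uniform(0, 1, 1000)
        n_bins = 10
        d = equal_width_discretize(x, n_bins)
        lo, hi = x.min(), x.max()
        w = (hi - lo) / n_bins
        for xi, bi in zip(x, d.bins):
            # brute-force per-element interval search: right-open bins,
            # final bin closed at the maximum
            expected = n_bins if xi == hi else int((xi - lo) // w) + 1
            expected = min(expected, n_bins)
            assert bi == expected

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            equal_width_discretize([2.0, 2.0, 2.0], 2)

    def test_edges_equal_width(self):
        d = equal_width_discretize([0.0, 10.0, 3.3, 7.1], 4)
        widths = np.diff(d.bin_edges)
        assert np.allclose(widths, widths[0])


class TestEntropy:
    def test_uniform_two_levels(self):
        h = entropy([1, 1, 1, 2, 2, 2])
        assert h.value == pytest.approx(np.log(2))

    def test_single_level_zero_for_both_estimators(self):
        assert entropy([1, 1, 1], "plugin").value == 0.0
        assert entropy([1, 1, 1], "miller_madow").value == 0.0

    def test_counts_3_1_both_estimators(self):
        labels = [1, 1, 1, 2]
        plugin = entropy(labels, "plugin").value
        assert plugin == pytest.approx(entropy_oracle([3, 1]), abs=1e-12)
        mm = entropy(labels, "miller_madow").value
        assert mm == pytest.approx(plugin + 1 / 8, abs=1e-12)

    def test_joint_degenerate_diagonal(self):
        dx = [1, 2, 1, 2, 2]
        assert joint_entropy(dx, dx).value == pytest.approx(entropy(dx).value)

    def test_joint_independent_uniform(self):
        dx = [1, 1, 2, 2]
        dy = [1, 2, 1, 2]
        assert joint_entropy(dx, dy).value == pytest.approx(np.log(4))

    def test_joint_matches_cellwise_oracle(self):
        dx = [1, 1, 1, 2, 2, 2]
        dy = [1, 1, 2, 1, 2, 2]  # table [[2,1],[1,2]]
        assert joint_entropy(dx, dy).value == pytest.approx(
            entropy_oracle([2, 1, 1, 2]), abs=1e-12
        )


DX = [1, 1, 1, 2, 2, 2]
DY = [1, 1, 2, 1, 2, 2]  # joint counts [[2,1],[1,2]], m=6


class TestMutualInformation:
    def test_self_information_is_entropy(self):
        assert mutual_information(DX, DX) == pytest.approx(entropy(DX).value)

    def test_table_2112_value(self):
        expected = mi_plugin_oracle([[2, 1], [1, 2]])
        assert expected == pytest.approx(0.05663, abs=5e-6)
        assert mutual_information(DX, DY) == pytest.approx(expected, abs=1e-12)

    def test_constant_partner_gives_zero(self):
        assert mutual_information(DX, [1] * 6) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            mutual_information([1, 2], [1, 2, 3])


class TestLRT:
    def test_independent_table_zero(self):
        assert lrt_statistic([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_identity_with_plugin_mi(self):
        assert lrt_statistic(DX, DY) == pytest.approx(
            12 * mutual_information(DX, DY), abs=1e-10
        )
        assert lrt_statistic(DX, DY) == pytest.approx(0.6796, abs=5e-4)

    def test_balanced_self_pair(self):
        assert lrt_statistic(DX, DX) == pytest.approx(2 * 6 * np.log(2))


@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_mi_lrt_identity_and_entropy_bounds_random_tables(seed):
    """MI_plugin = LRT/(2m) and min/mean/max entropy bounds on random data."""
    gen = np.random.default_rng(seed)
    m = int(gen.integers(6, 60))
    dx = gen.integers(1, gen.integers(2, 6), size=m)
    dy = gen.integers(1, gen.integers(2, 6), size=m)
    if len(set(dx)) < 2 or len(set(dy)) < 2:
        dx[0], dy[0] = dx.max() + 1, dy.max() + 1
    mi = mutual_information(dx, dy, "plugin")
    assert mi == pytest.approx(lrt_statistic(dx, dy) / (2 * m), abs=1e-10)
    hx = entropy(dx, "plugin").value
    hy = entropy(dy, "plugin").value
    tol = 1e-12
    assert mi <= min(hx, hy) + tol <= (hx + hy) / 2 + 2 * tol <= max(hx, hy) + 3 * tol
    assert mutual_information(dy, dx, "plugin") == pytest.approx(mi, abs=1e-12)
    # Miller-Madow exceeds plugin by exactly (B+ - 1)/(2m) for marginals
    mm = entropy(dx, "miller_madow").value
    b_plus = len(np.unique(dx))
    assert mm == pytest.approx(hx + (b_plus - 1) / (2 * m), abs=1e-12)


class TestMiMatrix:
    def test_identical_genes_share_entropy(self):
        expr = np.vstack([np.arange(16.0), np.arange(16.0)])
        mi = mi_matrix(expr, n_bins=4, estimator="plugin")
        assert mi.iloc[0, 1] == pytest.approx(mi.iloc[0, 0])

    def test_matches_looped_pairwise_calls(self, small_expr):
        mi = mi_matrix(small_expr, n_bins=5, estimator="miller_madow")
        for i in range(6):
            for j in range(6):
                di = equal_width_discretize(small_expr.iloc[i], 5).bins
                dj = equal_width_discretize(small_expr.iloc[j], 5).bins
                if i == j:
                    expected = entropy(di, "miller_madow").value
                else:
                    expected = mutual_information(di, dj, "miller_madow")
                assert mi.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_plugin_entries_nonnegative(self, small_expr):
        mi = mi_matrix(small_expr, n_bins=4, estimator="plugin")
        assert (mi.to_numpy() >= 0).all()

    def test_constant_gene_rejected(self, small_expr):
        bad = small_expr.copy()
        bad.loc["g2"] = 3.0
        with pytest.raises(DegenerateInputError, match="g2"):
            mi_matrix(bad)


def test_contingency_table_counts():
    t = contingency_table(DX, DY)
    assert t.tolist() == [[2, 1], [1, 2]]
    assert t.sum() == 6
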