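import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet import (
    DegenerateInputError,
    bicor,
    cor_matrix,
    cor_pvalue,
    discordance_screen,
    pearson_cor,
    spearman_cor,
)
from coexnet.correlation import _bicor_terms

from oracles import bicor_oracle, pearson_oracle


class TestPearsonSpearman:
    def test_exact_linear_relationships(self):
        assert pearson_cor([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_cor([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_sum_of_products_oracle(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        assert pearson_cor(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_spearman_monotone_invariance(self):
        assert spearman_cor([1, 2, 3], [1, 8, 27]) == pytest.approx(1.0)
        assert spearman_cor([1, 2, 3], [9, 4, 1]) == pytest.approx(-1.0)

    def test_spearman_ties_via_midrank_oracle(self):
        from scipy.stats import rankdata

        x, y = [1, 1, 2, 3], [4, 4, 5, 6]
        expected = pearson_oracle(rankdata(x), rankdata(y))
        assert spearman_cor(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_cor([1, 1, 1], [1, 2, 3])


class TestBicor:
    def test_affine_relationship_gives_unity(self):
        assert bicor([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)

    def test_negation_flips_sign(self):
        assert bicor([1, 2, 3, 4, 5], [-1, -2, -3, -4, -5]) == pytest.approx(-1.0)

    def test_outlier_case_matches_literal_equations(self):
        # max_p_outliers=0.5 disables proportion capping, so the value must
        # equal the plain median/MAD/biweight formula; the point x=100 has
        # |u| = 97/9 > 1 and weight exactly 0.
        x = np.array([1.0, 2, 3, 4, 100])
        y = np.array([1.0, 2, 3, 4, 5])
        got = bicor(x, y, max_p_outliers=0.5)
        assert got == pytest.approx(bicor_oracle(x, y), abs=1e-12)
        terms = _bicor_terms(x, 0.5)
        assert terms[-1] == 0.0

    def test_weights_zero_exactly_beyond_nine_mads(self, rng):
        x = rng.standard_normal(100)
        x[0] = 50.0  # > 9 mads out
        terms = _bicor_terms(x, 0.5)
        med, mad = np.median(x), np.median(np.abs(x - np.median(x)))
        far = np.abs(x - med) >= 9 * mad
        assert (terms[far] == 0).all()
        w = terms[~far] / (x[~far] - med)
        assert ((w >= 0) & (w <= 1)).all()

    def test_capping_bounds_zero_weight_fraction(self, rng):
        # heavy upper tail: without capping ~10% of points get weight 0
        x = np.concatenate([rng.standard_normal(900), 200 + rng.standard_normal(100)])
        terms = _bicor_terms(x, 0.02)
        med = np.median(x)
        upper = x > med
        zero_frac = (terms[upper] == 0).mean()
        assert zero_frac <= 0.25  # capped well below the uncapped ~0.2 of the side
        uncapped = _bicor_terms(x, 0.5)
        assert (uncapped[upper] == 0).mean() > zero_frac

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_positive_affine_invariance(self, a, b, seed):
        gen = np.random.default_rng(seed)
        x = gen.standard_normal(30)
        y = gen.standard_normal(30)
        r0 = bicor(x, y)
        assert bicor(a * x + b, y) == pytest.approx(r0, abs=1e-9)
        assert bicor(-x, y) == pytest.approx(-r0, abs=1e-9)

    def test_mad_zero_falls_back_to_pearson_terms(self):
        # both vectors have mad 0 but positive sd, so both fall back to
        # mean-centred unit-weight terms and bicor reduces to Pearson
        x = np.array([0.0, 0, 0, 0, 0, 0, 1, 2])
        y = np.array([0.0, 0, 0, 0, 0, 0, 2, 1])
        got = bicor(x, y)
        assert got == pytest.approx(pearson_cor(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            bicor([1.0, 1, 1, 1], [1.0, 2, 3, 4])


class TestCorMatrix:
    @pytest.mark.parametrize("method", ["pearson", "spearman", "bicor"])
    def test_identical_rows_fully_correlated(self, method):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5]], index=["a", "b"]
        )
        c = cor_matrix(expr, method=method)
        assert c.loc["a", "b"] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "bicor"])
    def test_matrix_matches_pairwise_loop(self, small_expr, method):
        c = cor_matrix(small_expr, method=method)
        fn = {"pearson": pearson_cor, "spearman": spearman_cor, "bicor": bicor}[method]
        for i in range(6):
            for j in range(i + 1, 6):
                expected = fn(small_expr.iloc[i], small_expr.iloc[j])
                assert c.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_constant_gene_listed_in_error(self, small_expr):
        bad = small_expr.copy()
        bad.loc["g3"] = 1.0
        with pytest.raises(DegenerateInputError, match="g3"):
            cor_matrix(bad)

    def test_bicor_close_to_pearson_on_gaussian_data(self, rng):
        m = 1000
        diffs = []
        for _ in range(50):
            x = rng.standard_normal(m)
            y = 0.5 * x + rng.standard_normal(m)
            diffs.append(abs(bicor(x, y) - pearson_cor(x, y)))
        assert np.mean(diffs) < 0.05


class TestCorPvalue:
    def test_boundary_values(self):
        assert cor_pvalue(0.0, 30) == pytest.approx(1.0)
        assert cor_pvalue(1.0, 30) == 0.0
        assert cor_pvalue(-1.0, 30) == 0.0

    def test_matches_t_cdf_oracle(self):
        from scipy.stats import t as tdist

        r, m = 0.5, 30
        tval = r * np.sqrt((m - 2) / (1 - r**2))
        expected = 2 * (1 - tdist.cdf(abs(tval), m - 2))
        assert cor_pvalue(r, m) == pytest.approx(expected, rel=1e-10)


class TestDiscordanceScreen:
    def _mats(self, n, rng):
        c = rng.uniform(-1, 1, (n, n))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        return c, a

    def test_z_scores_standardized(self, rng):
        c, a = self._mats(10, rng)
        pairs = discordance_screen(c, a, z_threshold=np.inf)
        assert len(pairs) == 2
        # with a vacuous constraint the screen reduces to the global argmax
        iu, ju = np.triu_indices(10, k=1)
        mi_vals = a[iu, ju]
        k = np.argmax(mi_vals)
        mi_pair = next(p for p in pairs if p.kind == "mi")
        assert mi_pair.mi_adjacency_value == pytest.approx(mi_vals[k])

    def test_planted_outlier_pair_found(self):
        # gene pair (g3, g4): no linear relation but identical binned
        # pattern -> high MI adjacency, low |cor|
        n = 6
        cor = np.full((n, n), 0.8)
        np.fill_diagonal(cor, 1.0)
        cor[2, 3] = cor[3, 2] = 0.01
        adj = np.full((n, n), 0.2)
        np.fill_diagonal(adj, 1.0)
        adj[2, 3] = adj[3, 2] = 0.95
        pairs = discordance_screen(cor, adj, z_threshold=1.9)
        mi_pair = next(p for p in pairs if p.kind == "mi")
        assert {mi_pair.id_a, mi_pair.id_b} == {"g3", "g4"}

    def test_too_few_genes_rejected(self):
        with pytest.raises(Exception):
            discordance_screen(np.ones((1, 1)), np.ones((1, 1)))
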