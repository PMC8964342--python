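"""Parameter transforms, Dirichlet-multinomial likelihood, and OTU table I/O."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msneutral import (
    CommunityMatrix,
    MetacommunityState,
    PriorSpec,
    immigration_from_m,
    m_from_immigration,
    metacommunity_log_likelihood,
    read_biom_json,
    read_otu_table,
    site_log_likelihood,
    theta_from_speciation,
    write_otu_table,
)


class TestTransforms:
    @pytest.mark.parametrize("m,n,expected", [
        (0.5, 2, 1.0),
        (0.05, 2500, 2499 * 0.05 / 0.95),
    ])
    def test_immigration_from_m_values(self, m, n, expected):
        assert immigration_from_m(m, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("I,n,expected", [
        (1.0, 2, 0.5),
        (2499 * 0.05 / 0.95, 2500, 0.05),
    ])
    def test_m_from_immigration_values(self, I, n, expected):
        assert m_from_immigration(I, n) == pytest.approx(expected, rel=1e-12)

    def test_theta_from_speciation_values(self):
        assert theta_from_speciation(0.5, 3) == pytest.approx(2.0)
        assert theta_from_speciation(0.01, 10001) == pytest.approx(
            0.01 / 0.99 * 10000, rel=1e-12)

    @given(m=st.floats(1e-6, 1 - 1e-6), n=st.integers(2, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_and_monotonicity(self, m, n):
        I = immigration_from_m(m, n)
        assert m_from_immigration(I, n) == pytest.approx(m, rel=1e-9)
        if m < 0.999:
            assert immigration_from_m(m + 1e-6, n) > I  # order-preserving

    @pytest.mark.parametrize("bad_m", [0.0, 1.0, -0.2, 1.5])
    def test_boundaries_rejected(self, bad_m):
        with pytest.raises(ValueError):
            immigration_from_m(bad_m, 100)
        with pytest.raises(ValueError):
            theta_from_speciation(bad_m, 100)
        with pytest.raises(ValueError):
            m_from_immigration(0.0, 100)


class TestSiteLikelihood:
    def test_single_read_equals_frequency(self):
        ll = site_log_likelihood(np.array([1, 0]), 7.3, np.array([0.4, 0.6]))
        assert ll == pytest.approx(math.log(0.4), rel=1e-12)

    def test_polya_urn_enumeration_two_reads(self):
        beta = np.array([0.5, 0.5])
        probs = [math.exp(site_log_likelihood(np.array(x), 1.0, beta))
                 for x in [(2, 0), (1, 1), (0, 2)]]
        assert probs == pytest.approx([0.375, 0.25, 0.375], rel=1e-12)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_large_immigration_approaches_multinomial(self):
        x = np.array([3, 5, 2])
        beta = np.array([0.2, 0.5, 0.3])
        big = site_log_likelihood(x, 1e6, beta)
        from scipy.stats import multinomial
        assert big == pytest.approx(
            multinomial.logpmf(x, n=10, p=beta), abs=1e-4)

    @pytest.mark.parametrize("I", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("S", [2, 3])
    @pytest.mark.parametrize("J", [1, 2, 4])
    def test_normalization_by_enumeration(self, I, S, J):
        """Probabilities over all count vectors of total J sum to one."""
        rng = np.random.default_rng(S * 10 + J)
        beta = rng.dirichlet(np.ones(S))
        total = 0.0
        for combo in itertools.product(range(J + 1), repeat=S):
            if sum(combo) == J:
                total += math.exp(site_log_likelihood(np.array(combo), I, beta))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zero_mass_positive_count_is_minus_inf(self):
        ll = site_log_likelihood(np.array([1, 1]), 1.0, np.array([0.0, 1.0]))
        assert ll == -np.inf

    def test_finite_across_immigration_scales(self):
        x = np.array([10, 5, 0])
        beta = np.array([0.3, 0.2, 0.5])
        for I in np.logspace(-3, 6, 12):
            assert np.isfinite(site_log_likelihood(x, float(I), beta))

    def test_beta_may_include_unrepresented_mass(self):
        x = np.array([2, 3])
        full = np.array([0.3, 0.5, 0.2])  # trailing unobserved category
        assert np.isfinite(site_log_likelihood(x, 2.0, full))


class TestMetacommunityLikelihood:
    def test_single_site_reduces_to_site_likelihood(self, small_matrix):
        X1 = small_matrix.subset_sites([small_matrix.site_ids[0]])
        beta = np.ones(X1.n_taxa) / X1.n_taxa
        assert metacommunity_log_likelihood(X1, np.array([2.0]), beta) == (
            pytest.approx(site_log_likelihood(X1.counts[0], 2.0, beta)))

    def test_site_permutation_invariance(self):
        counts = np.array([[2, 0], [0, 2]])
        X = CommunityMatrix(counts, ["a", "b"], ["t1", "t2"])
        Xr = CommunityMatrix(counts[::-1], ["b", "a"], ["t1", "t2"])
        beta = np.array([0.5, 0.5])
        I = np.array([1.0, 1.0])
        v1 = metacommunity_log_likelihood(X, I, beta)
        assert v1 == pytest.approx(metacommunity_log_likelihood(Xr, I, beta))
        assert v1 == pytest.approx(2 * math.log(0.375), rel=1e-12)


class TestTypes:
    def test_all_zero_taxa_are_dropped(self):
        X = CommunityMatrix(np.array([[1, 0, 2], [3, 0, 0]]),
                            ["s1", "s2"], ["a", "b", "c"])
        assert X.taxon_ids == ["a", "c"]
        assert X.counts.shape == (2, 2)

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            CommunityMatrix(np.array([[1, 0], [0, 0]]), ["s1", "s2"], ["a", "b"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CommunityMatrix(np.array([[1, -1]]), ["s1"], ["a", "b"])

    def test_metacommunity_state_mass_balance(self):
        MetacommunityState(2.0, np.array([0.3, 0.6]), 0.1)
        with pytest.raises(ValueError):
            MetacommunityState(2.0, np.array([0.3, 0.6]), 0.2)

    def test_prior_spec_positivity(self):
        with pytest.raises(ValueError):
            PriorSpec(theta_shape=0.0)


class TestIO:
    def test_tsv_round_trip(self, small_matrix, tmp_path):
        p = tmp_path / "otu.tsv"
        write_otu_table(small_matrix, p)
        back = read_otu_table(p)
        assert back.site_ids == small_matrix.site_ids
        assert back.taxon_ids == small_matrix.taxon_ids
        np.testing.assert_array_equal(back.counts, small_matrix.counts)

    def test_transposed_layout(self, small_matrix, tmp_path):
        p = tmp_path / "otu_t.tsv"
        write_otu_table(small_matrix, p, taxa_as_rows=False)
        back = read_otu_table(p, taxa_as_rows=False)
        np.testing.assert_array_equal(back.counts, small_matrix.counts)

    def test_non_integer_cells_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("taxon_id\ts1\ts2\nA\t1.5\t2\nB\t0\t1\n")
        with pytest.raises(ValueError):
            read_otu_table(p)

    @pytest.mark.parametrize("matrix_type", ["dense", "sparse"])
    def test_biom_json(self, tmp_path, matrix_type):
        counts = np.array([[5, 0], [1, 2], [0, 3]])  # taxa x samples
        doc = {
            "shape": [3, 2],
            "rows": [{"id": t} for t in ["A", "B", "C"]],
            "columns": [{"id": s} for s in ["s1", "s2"]],
            "matrix_type": matrix_type,
        }
        if matrix_type == "dense":
            doc["data"] = counts.tolist()
        else:
            doc["data"] = [[i, j, int(counts[i, j])]
                           for i in range(3) for j in range(2) if counts[i, j]]
        p = tmp_path / "table.biom"
        p.write_text(json.dumps(doc))
        X = read_biom_json(p)
        assert X.site_ids == ["s1", "s2"]
        np.testing.assert_array_equal(X.counts, counts.T)
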