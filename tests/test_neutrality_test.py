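"""Neutral simulators and the Monte Carlo pseudo-P machinery."""

import numpy as np
import pytest

from msneutral import (
    ChainSettings,
    immigration_from_m,
    pseudo_p,
    run_chain,
    run_neutrality_test,
    simulate_neutral_local,
    simulate_neutral_metacommunity,
    stick_breaking,
)
from msneutral.neutral_model import _sites_log_likelihood_given_sets
from msneutral.neutrality_test import _simulate_meta_counts


class TestStickBreaking:
    def test_mass_accounting(self):
        rng = np.random.default_rng(0)
        for theta in (0.5, 5.0, 80.0):
            w = stick_breaking(theta, rng)
            assert (w > 0).all()
            assert w.sum() <= 1.0
            assert 1.0 - w.sum() < 1e-6  # residual below truncation scale

    def test_small_theta_monodominance(self):
        rng = np.random.default_rng(1)
        firsts = [stick_breaking(0.001, rng)[0] for _ in range(50)]
        assert np.median(firsts) > 0.99

    def test_rejects_bad_theta(self):
        with pytest.raises(ValueError):
            stick_breaking(0.0, np.random.default_rng(0))


class TestSimulators:
    def test_meta_row_sums_exact(self):
        rng = np.random.default_rng(2)
        J = np.array([150, 400, 90])
        X = simulate_neutral_metacommunity(20.0, np.array([5.0, 9.0, 2.0]), J, rng)
        np.testing.assert_array_equal(X.site_totals, J)

    def test_meta_small_theta_single_taxon_dominates(self):
        rng = np.random.default_rng(3)
        shares = []
        for _ in range(50):
            X = simulate_neutral_metacommunity(
                0.001, np.array([5.0]), np.array([500]), rng)
            shares.append(X.counts.max() / 500)
        assert np.median(shares) > 0.99

    def test_local_row_sums_and_novel_taxa(self):
        rng = np.random.default_rng(4)
        beta = np.array([0.5, 0.2, 0.3])  # last entry is unrepresented mass
        J = np.array([300, 300])
        X = simulate_neutral_local(beta, 10.0, np.array([20.0, 20.0]), J, rng)
        np.testing.assert_array_equal(X.site_totals, J)
        assert any(t.startswith("novel") for t in X.taxon_ids)

    def test_local_high_immigration_tracks_beta(self):
        rng = np.random.default_rng(5)
        beta = np.concatenate([np.full(10, 0.0999), [0.001]])
        X = simulate_neutral_local(beta, 5.0, np.array([1e6]), np.array([10_000]), rng)
        freq = np.zeros(10)
        for t, c in zip(X.taxon_ids, X.counts[0]):
            if t.startswith("taxon"):
                freq[int(t[5:])] = c / 10_000
        assert 0.5 * np.abs(freq - 0.0999).sum() < 0.05

    def test_local_low_immigration_monodominant(self):
        rng = np.random.default_rng(6)
        beta = np.concatenate([np.full(10, 0.0999), [0.001]])
        shares = []
        for _ in range(30):
            X = simulate_neutral_local(beta, 5.0, np.array([0.01]),
                                       np.array([500]), rng)
            shares.append(X.counts[0].max() / 500)
        assert np.median(shares) > 0.95


class TestPseudoP:
    def test_extremes(self):
        r = pseudo_p(-10.0, np.array([-5.0, -4.0, -3.0]))
        assert r["pseudo_P"] == 0.0 and r["pseudo_P_complement"] == 1.0
        r = pseudo_p(-1.0, np.array([-5.0, -4.0, -3.0]))
        assert r["pseudo_P"] == 1.0

    def test_median_with_tie_rule(self):
        L = np.arange(2500, dtype=float)
        r = pseudo_p(float(np.median(L)), L)
        assert r["n_below"] == 1250  # ties count as below
        assert r["pseudo_P"] == pytest.approx(1250 / 2500)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pseudo_p(0.0, np.array([1.0, np.inf]))
        with pytest.raises(ValueError):
            pseudo_p(np.nan, np.array([1.0]))

    def test_taxon_relabeling_invariance(self, small_matrix, quick_settings):
        """Renaming taxa leaves the pseudo-P bit-identical; permuting the
        columns (which only reorders arithmetic and RNG consumption) leaves
        it unchanged up to Monte Carlo noise."""
        from msneutral.neutral_model import CommunityMatrix

        _, trace = run_chain(small_matrix, quick_settings)
        r1 = run_neutrality_test(small_matrix, trace, "local",
                                 np.random.default_rng(7))
        renamed = CommunityMatrix(small_matrix.counts.copy(),
                                  list(small_matrix.site_ids),
                                  [f"x{t}" for t in small_matrix.taxon_ids])
        r1b = run_neutrality_test(renamed, trace, "local",
                                  np.random.default_rng(7))
        assert r1.pseudo_P == r1b.pseudo_P

        perm = np.random.default_rng(0).permutation(small_matrix.n_taxa)
        Xp = CommunityMatrix(small_matrix.counts[:, perm],
                             list(small_matrix.site_ids),
                             [small_matrix.taxon_ids[j] for j in perm])
        trace.beta = np.concatenate(
            [trace.beta[:, :-1][:, perm], trace.beta[:, -1:]], axis=1)
        trace.taxon_ids = [trace.taxon_ids[j] for j in perm]
        r2 = run_neutrality_test(Xp, trace, "local", np.random.default_rng(7))
        assert abs(r1.pseudo_P - r2.pseudo_P) < 0.15

    def test_depth_mismatch_rejected(self, small_matrix, quick_settings):
        _, trace = run_chain(small_matrix, quick_settings)
        trace.site_totals = trace.site_totals + 1
        with pytest.raises(ValueError):
            run_neutrality_test(small_matrix, trace, "local",
                                np.random.default_rng(0))


def test_known_parameter_pseudo_p_is_uniform():
    """Under the null with known parameters the pseudo-P is ~ Uniform(0,1)."""
    rng = np.random.default_rng(7)
    theta, J, M = 30.0, 500, 3
    I = np.full(M, immigration_from_m(0.05, J))
    Jv = np.full(M, J, dtype=np.int64)

    def one_loglik():
        counts, full = _simulate_meta_counts(theta, I, Jv, rng)
        pos = counts.sum(axis=0) > 0
        pos[-1] = True
        return _sites_log_likelihood_given_sets(
            counts[:, pos], I[None, :], full[None, pos])[0]

    ps = []
    for _ in range(120):
        L0 = one_loglik()
        sims = np.array([one_loglik() for _ in range(120)])
        ps.append((sims <= L0).mean())
    ps = np.asarray(ps)
    for q in np.arange(0.1, 1.0, 0.1):
        assert abs((ps <= q).mean() - q) < 0.15


def test_fitted_verdicts_agree_across_levels():
    """Meta- and local-level tests both pass on data from the full model."""
    rng = np.random.default_rng(8)
    I = np.full(3, immigration_from_m(0.05, 800))
    X = simulate_neutral_metacommunity(40.0, I, np.full(3, 800, dtype=np.int64), rng)
    _, trace = run_chain(X, ChainSettings(n_iterations=1500, n_burnin=750,
                                          thinning=3, seed=4))
    meta = run_neutrality_test(X, trace, "metacommunity", np.random.default_rng(1))
    local = run_neutrality_test(X, trace, "local", np.random.default_rng(2))
    assert meta.neutral_compatible and local.neutral_compatible
    assert meta.n_total == trace.n_sets
    assert meta.pseudo_P_complement == pytest.approx(1 - meta.pseudo_P)
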