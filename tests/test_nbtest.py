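"""Size factors, dispersion estimation, and the exact conditional NB test.

The exact test is checked against an independently coded brute-force
oracle (explicit double loop over splits with a gammaln-based pmf) and
against the closed-form binomial conditional law in the Poisson limit.
"""

import math

import numpy as np
import pytest
from scipy import stats

from replicall.nbtest import (
    estimate_dispersions,
    estimate_size_factors,
    nb_exact_pvalue,
    nb_exact_pvalues,
)
from replicall.nbtest import TestInput as NBTestInput

# ---------------------------------------------------------------- oracle


def _pmf(k, mean, var):
    """NB (mean/variance parameterization) or Poisson pmf, coded from scratch."""
    if mean == 0:
        return 1.0 if k == 0 else 0.0
    if var <= mean * (1 + 1e-12):  # Poisson
        return math.exp(-mean + k * math.log(mean) - math.lgamma(k + 1))
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return math.exp(
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log(1 - p)
    )


def oracle_pvalue(K_A, K_B, alpha, s_A, s_B, sided="one_sided_enrichment"):
    """Direct summation over all splits of T; independent of the implementation."""
    T = K_A + K_B
    if T == 0:
        return 1.0
    S_A, S_B = sum(s_A), sum(s_B)
    q = T / (S_A + S_B)
    mA, mB = q * S_A, q * S_B
    vA = mA + alpha * sum(x * x for x in s_A) * q * q
    vB = mB + alpha * sum(x * x for x in s_B) * q * q
    probs = []
    for a in range(T + 1):
        probs.append(_pmf(a, mA, vA) * _pmf(T - a, mB, vB))
    total = sum(probs)
    if sided == "one_sided_enrichment":
        num = sum(probs[a] for a in range(K_A, T + 1))
    else:
        obs = probs[K_A]
        num = sum(p for p in probs if p <= obs * (1 + 1e-9))
    return num / total


def pvalue(K_A, K_B, alpha, s_A, s_B, sided="one_sided_enrichment"):
    t = NBTestInput(
        k_sample=np.array([K_A]), k_control=np.array([K_B]),
        s_sample=np.asarray(s_A, float), s_control=np.asarray(s_B, float),
        alpha=alpha,
    )
    return nb_exact_pvalue(t, sided=sided)


# ---------------------------------------------------------------- tests


class TestSizeFactors:
    def test_identical_depths_give_unit_factors(self):
        d = np.full((5, 3), 800)
        s = estimate_size_factors(d).size_factors
        assert np.allclose(s, 1.0)

    def test_proportional_depths(self):
        d = np.array([[100, 200], [200, 400]])
        s = estimate_size_factors(d).size_factors
        assert np.allclose(s, [math.sqrt(0.5), math.sqrt(2)], atol=1e-4)

    def test_single_replicate_normalizes_to_one(self):
        d = np.array([[123], [456]])
        s = estimate_size_factors(d).size_factors
        assert np.allclose(s, [1.0])

    def test_no_common_coverage_is_an_error(self):
        d = np.array([[0, 10], [10, 0]])
        with pytest.raises(ValueError, match="covered"):
            estimate_size_factors(d)


class TestDispersionEstimation:
    def test_zero_variance_floors_at_trend(self):
        counts = np.vstack([np.array([10, 10]), np.random.default_rng(0).poisson(5, (50, 2))])
        model = estimate_dispersions(counts, np.ones(2))
        assert model.alpha_hat[0] == 0.0
        assert model.alpha[0] == pytest.approx(model.trend(model.mu[0]))

    def test_moment_arithmetic(self):
        counts = np.vstack([[5, 15], np.random.default_rng(0).poisson(5, (50, 2))])
        model = estimate_dispersions(counts, np.ones(2))
        # mu = 10, w = 50, xi = 1 -> (50 - 10) / 100
        assert model.alpha_hat[0] == pytest.approx(0.4)
        assert model.mu[0] == pytest.approx(10.0)

    def test_sub_poisson_clamps_to_zero(self):
        counts = np.vstack([[8, 12], np.random.default_rng(0).poisson(5, (50, 2))])
        model = estimate_dispersions(counts, np.ones(2))
        assert model.alpha_hat[0] == 0.0
        assert model.alpha_raw[0] == pytest.approx((8 - 10) / 100)

    def test_maximum_sharing_dominates_both_terms(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, (100, 4))
        model = estimate_dispersions(counts, np.ones(4), sharing_mode="maximum")
        assert (model.alpha >= model.alpha_hat - 1e-15).all()
        assert (model.alpha >= model.trend(model.mu) - 1e-15).all()

    def test_final_alpha_monotone_in_empirical_estimate(self):
        # same control mean, increasing scatter: alpha must not decrease
        spreads = [(10, 10), (9, 11), (7, 13), (5, 15), (2, 18), (0, 20)]
        for mode in ("outlier", "maximum"):
            counts = np.array(spreads, dtype=float)
            model = estimate_dispersions(counts, np.ones(2), sharing_mode=mode)
            order = np.argsort(model.alpha_hat)
            final = model.alpha[order]
            assert (np.diff(final) >= -1e-12).all(), mode

    def test_single_control_uses_fallback_trend(self):
        counts = np.array([[3], [0], [7]], dtype=float)
        model = estimate_dispersions(
            counts, np.ones(1), fallback_trend=(0.02, 0.7)
        )
        assert (model.a0, model.a1) == (0.02, 0.7)
        assert model.alpha[0] == pytest.approx(0.02 + 0.7 / 3.0)

    def test_sample_inconsistency_escalates_dispersion(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(0.5, (200, 4))
        consistent = np.full((200, 4), 5)
        burst = consistent.copy()
        burst[0] = [0, 1, 20, 0]  # one replicate carries nearly all signal
        base = estimate_dispersions(counts, np.ones(4),
                                    sample_counts=consistent,
                                    sample_size_factors=np.ones(4))
        esc = estimate_dispersions(counts, np.ones(4),
                                   sample_counts=burst,
                                   sample_size_factors=np.ones(4))
        assert esc.alpha[0] > base.alpha[0]
        assert esc.outlier[0]


class TestPooledConditionCounts:
    def test_strands_summed_per_replicate(self, small_sim):
        from replicall.nbtest import pooled_condition_counts

        m = small_sim.matrix
        norm = __import__("replicall").estimate_size_factors(m.position_depth_matrix())
        t = pooled_condition_counts(m, 0, norm, alpha=0.1)
        assert t.K_A == int(m.sample_fwd[0].sum() + m.sample_rev[0].sum())
        assert t.K_B == int(m.control_fwd[0].sum() + m.control_rev[0].sum())
        assert t.T == t.K_A + t.K_B
        assert len(t.k_sample) == len(m.sample_labels)

    def test_all_zero_row_gives_empty_totals(self):
        import numpy as np

        from replicall.nbtest import TestInput as TI

        t = TI(k_sample=np.zeros(4, int), k_control=np.zeros(4, int),
               s_sample=np.ones(4), s_control=np.ones(4), alpha=0.0)
        assert t.K_A == t.K_B == t.T == 0


class TestExactPvalue:
    def test_empty_evidence_gives_one(self):
        assert pvalue(0, 0, 0.3, [1, 1], [1, 1]) == 1.0

    def test_poisson_limit_extreme_split(self):
        # alpha = 0, symmetric: P(K_A = T = 5) = (1/2)^5
        p = pvalue(5, 0, 0.0, [1.0], [1.0])
        assert p == pytest.approx(0.03125, abs=1e-12)

    @pytest.mark.parametrize("K_A,K_B", [(0, 0), (3, 2), (10, 0), (0, 10), (7, 13)])
    @pytest.mark.parametrize("s_A,s_B", [([1, 1], [1, 1]), ([0.5, 1.5], [2.0, 1.0, 0.8])])
    def test_poisson_limit_matches_binomial_tail(self, K_A, K_B, s_A, s_B):
        T = K_A + K_B
        frac = sum(s_A) / (sum(s_A) + sum(s_B))
        expected = stats.binom.sf(K_A - 1, T, frac) if T > 0 else 1.0
        assert pvalue(K_A, K_B, 0.0, s_A, s_B) == pytest.approx(expected, abs=1e-10)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            K_A = int(rng.integers(0, 80))
            K_B = int(rng.integers(0, 80))
            alpha = float(rng.choice([0.0, 0.05, 0.3, 1.5]))
            s_A = list(rng.uniform(0.5, 2.0, size=int(rng.integers(1, 5))))
            s_B = list(rng.uniform(0.5, 2.0, size=int(rng.integers(2, 5))))
            for sided in ("one_sided_enrichment", "two_sided"):
                expected = oracle_pvalue(K_A, K_B, alpha, s_A, s_B, sided)
                got = pvalue(K_A, K_B, alpha, s_A, s_B, sided)
                assert got == pytest.approx(expected, abs=1e-10), (K_A, K_B, alpha, sided)

    def test_one_sided_monotone_in_sample_count(self):
        for alpha in (0.0, 0.2, 1.0):
            for K_B in (0, 3, 15):
                ps = [pvalue(k, K_B, alpha, [1] * 4, [1] * 4) for k in range(40)]
                assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_large_totals_use_tail_approximation(self):
        # beyond the enumeration cap the p-value must stay a sane tail prob
        p_far = nb_exact_pvalues(
            np.array([12_000]), np.array([20_000]), np.array([0.01]),
            4.0, 4.0, 4.0, 4.0, max_enumeration=10_000,
        )[0]
        assert 0.0 <= p_far < 1e-6
        p_null = nb_exact_pvalues(
            np.array([10_000]), np.array([20_000]), np.array([0.01]),
            4.0, 4.0, 4.0, 4.0, max_enumeration=10_000,
        )[0]
        assert 0.3 < p_null <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_pvalues(np.array([5]), np.array([3]), np.array([0.0]),
                             1.0, 1.0, 1.0, 1.0)


class TestTypeIError:
    def test_null_simulation_p_value_calibration(self):
        """On null data (shared artifacts, no truth) raw one-sided p < 0.01
        must occur for at most 2% of ~10,000 variant tests."""
        from replicall.calling import CallerConfig, call_variants
        from replicall.simulate import SimConfig, simulate_counts

        cfg = SimConfig(panel_bp=2500, n_truth=0, seed=42)
        sim = simulate_counts(cfg)
        results = call_variants(sim.matrix, CallerConfig(), panel=sim.panel)
        n_small = sum(1 for r in results if r.p < 0.01)
        assert len(results) > 5000
        assert n_small / len(results) <= 0.02
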