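"""BH adjustment, strand-bias and AF filters, and full call assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from replicall.calling import (
    CallerConfig,
    bh_adjust,
    call_variants,
    mean_allele_frequency,
    sbf_magnitude,
    strand_bias_factor,
)
from replicall.matrix import CountMatrix, VariantClass, VariantKey
from replicall.pileup import PanelRegion


class TestBHAdjust:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.04], m=1)[0] == pytest.approx(0.04)

    def test_running_minimum_from_the_right(self):
        adj = bh_adjust([0.01, 0.02, 0.03], m=3)
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_family_larger_than_observed(self):
        adj = bh_adjust([0.001, 0.5], m=4)
        assert np.allclose(adj, [0.004, 1.0])

    def test_m_below_count_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2, 0.3], m=2)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        extra=st.integers(0, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_independent_step_up(self, p, extra):
        """Against statsmodels' BH, with implicit p=1 tests made explicit."""
        m = len(p) + extra
        ours = bh_adjust(p, m=m)
        padded = np.concatenate([p, np.ones(extra)])
        theirs = multipletests(padded, method="fdr_bh")[1][: len(p)]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        assert (bh_adjust(p, m=500) >= p - 1e-15).all()


class TestStrandBias:
    def test_balanced_signal_passes(self):
        s = strand_bias_factor(0.004, 0.004)
        assert s == pytest.approx(1.0)
        assert sbf_magnitude(s) == pytest.approx(1.0)

    def test_exclusion_is_strictly_above_limit(self):
        # magnitude exactly 5 passes; 6 fails
        assert sbf_magnitude(strand_bias_factor(0.010, 0.002)) == pytest.approx(5.0)
        assert sbf_magnitude(strand_bias_factor(0.012, 0.002)) == pytest.approx(6.0)

    def test_one_silent_strand_is_infinite(self):
        assert sbf_magnitude(strand_bias_factor(0.01, 0.0)) == float("inf")
        assert sbf_magnitude(strand_bias_factor(0.0, 0.01)) == float("inf")

    def test_no_signal_on_either_strand_is_na(self):
        assert np.isnan(strand_bias_factor(0.0, 0.0))

    def test_invalid_af_rejected(self):
        with pytest.raises(ValueError):
            strand_bias_factor(1.5, 0.2)


class TestMeanAF:
    def test_unweighted_mean(self):
        assert mean_allele_frequency([5, 15], [5000, 5000]) == pytest.approx(0.002)

    def test_four_replicates(self):
        af = mean_allele_frequency([5, 5, 5, 5], [5000] * 4)
        assert af == pytest.approx(0.001)

    def test_differs_from_pooled_ratio_with_zero_count(self):
        af = mean_allele_frequency([10, 0], [5000, 5000])
        assert af == pytest.approx(0.001)

    def test_zero_depth_replicates_skipped(self):
        af = mean_allele_frequency([10, 7], [5000, 0])
        assert af == pytest.approx(0.002)

    def test_no_coverage_uncallable(self):
        assert np.isnan(mean_allele_frequency([0, 0], [0, 0]))


def _matrix(sample, control, depth=5000, pos=100, alt="T"):
    """Uniform-depth single-variant matrix with an even strand split."""
    sample = np.asarray(sample)[None, :]
    control = np.asarray(control)[None, :]
    ns, nc = sample.shape[1], control.shape[1]
    half = depth // 2
    return CountMatrix(
        variants=[VariantKey("chr1", pos, "A", alt, VariantClass.SNV)],
        sample_labels=[f"s{j}" for j in range(ns)],
        control_labels=[f"c{j}" for j in range(nc)],
        sample_fwd=sample // 2,
        sample_rev=sample - sample // 2,
        control_fwd=control // 2,
        control_rev=control - control // 2,
        sample_depth_fwd=np.full((1, ns), half),
        sample_depth_rev=np.full((1, ns), depth - half),
        control_depth_fwd=np.full((1, nc), half),
        control_depth_rev=np.full((1, nc), depth - half),
    )


PANEL = [PanelRegion("chr1", 1, 1000)]


class TestCallVariants:
    def test_consistent_enrichment_is_called(self):
        # ~1% AF in four sample replicates, silent controls
        m = _matrix([52, 48, 50, 55], [0, 0, 0, 0])
        (r,) = call_variants(m, CallerConfig(), panel=PANEL)
        assert r.call and r.adj_p < 0.05
        assert r.mean_af == pytest.approx(0.01, rel=0.15)

    def test_recurrent_artifact_is_rejected(self):
        # same elevated rate in both conditions: no enrichment
        m = _matrix([24, 26, 30, 22], [25, 27, 23, 28])
        (r,) = call_variants(m, CallerConfig(), panel=PANEL)
        assert not r.call
        assert "ADJ_P" in r.reasons

    def test_single_replicate_stochastic_error_is_rejected(self):
        # all evidence in one of four replicates
        m = _matrix([20, 0, 1, 0], [0, 0, 0, 0])
        (r,) = call_variants(m, CallerConfig(), panel=PANEL)
        assert not r.call

    def test_called_variants_point_in_the_right_direction(self):
        m = _matrix([0, 1, 0, 0], [30, 28, 33, 29])
        (r,) = call_variants(m, CallerConfig(), panel=PANEL)
        assert not r.call
        assert "DIRECTION" in r.reasons

    def test_strand_biased_signal_is_rejected(self):
        m = _matrix([50, 48, 52, 50], [0, 0, 0, 0])
        m.sample_fwd = m.sample_counts  # all support on one strand
        m.sample_rev = np.zeros_like(m.sample_fwd)
        (r,) = call_variants(m, CallerConfig(), panel=PANEL)
        assert not r.call
        assert "STRAND_BIAS" in r.reasons

    def test_af_threshold_applies_to_mean_af(self):
        m = _matrix([1, 1, 1, 1], [0, 0, 0, 0])  # 0.02% AF
        (r,) = call_variants(m, CallerConfig(af_threshold=5e-4), panel=PANEL)
        assert "LOW_AF" in r.reasons

    def test_m_tests_must_cover_universe(self):
        m = _matrix([5, 5, 5, 5], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="BH denominator"):
            call_variants(m, CallerConfig(m_tests=0), panel=PANEL)

    def test_filter_monotonicity(self, small_sim):
        """Raising the AF floor or lowering alpha never adds calls."""
        matrix, panel = small_sim.matrix, small_sim.panel

        def called(cfg):
            return {r.key for r in call_variants(matrix, cfg, panel=panel) if r.call}

        base = called(CallerConfig())
        assert called(CallerConfig(alpha=0.005)) <= base
        assert called(CallerConfig(af_threshold=5e-3)) <= base

    def test_direction_invariant_on_simulated_calls(self, small_sim):
        results = call_variants(small_sim.matrix, CallerConfig(), panel=small_sim.panel)
        s = np.array([r.k_sample.mean() for r in results if r.call])
        c = np.array([r.k_control.mean() for r in results if r.call])
        assert len(s) > 0 and (s > c).all()
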