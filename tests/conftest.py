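import io

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from replicall.matrix import build_matrix
from replicall.pileup import parse_mpileup
from replicall.simulate import SimConfig, emit_mpileup, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded simulation with SNV and deletion truth variants."""
    cfg = SimConfig(
        panel_bp=200,
        n_truth=4,
        truth_af_low=2e-3,
        truth_af_high=1e-2,
        truth_indel_fraction=0.5,
        seed=11,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_sim_pileups(small_sim):
    """The same simulation re-parsed from its emitted mpileup text."""

    def replicate(cond, j):
        buf = io.StringIO()
        emit_mpileup(small_sim, cond, j, buf)
        buf.seek(0)
        return list(parse_mpileup(buf, min_base_quality=30))

    cfg = small_sim.config
    samples = [replicate("sample", j) for j in range(cfg.n_sample)]
    controls = [replicate("control", j) for j in range(cfg.n_control)]
    return samples, controls


@pytest.fixture(scope="session")
def rebuilt_matrix(small_sim, small_sim_pileups):
    samples, controls = small_sim_pileups
    return build_matrix(samples, controls, panel=small_sim.panel)
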