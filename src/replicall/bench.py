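"""The standard synthetic benchmark.

One benchmark run simulates a 6,250 bp panel (25,000 variant tests) at
~5,000x depth with 4 sample and 4 control replicates, 20 spiked variants
with allele frequencies evenly spaced from 0.05% to 1% at 20 ng input
per replicate, and the default error landscape; it then runs the full
caller with default thresholds and scores calls against the spike truth.
Headline numbers are the mean sensitivity and mean false positives per
10,000 variant tests across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calling import CallerConfig, call_variants
from .matrix import tested_variant_space
from .metrics import EvalResult, evaluate
from .simulate import SimConfig, simulate_counts

BENCHMARK_CONFIG = SimConfig(
    panel_bp=6250,
    n_sample=4,
    n_control=4,
    depth=5000,
    input_ng=20.0,
    n_truth=20,
    truth_af_low=5e-4,
    truth_af_high=1e-2,
)


@dataclass
class BenchmarkRun:
    seed: int
    eval_result: EvalResult
    n_called: int


def run_benchmark(
    seed: int,
    sim_config: SimConfig | None = None,
    caller_config: CallerConfig | None = None,
) -> BenchmarkRun:
    cfg = replace(sim_config or BENCHMARK_CONFIG, seed=seed)
    sim = simulate_counts(cfg)
    results = call_variants(sim.matrix, caller_config or CallerConfig(), panel=sim.panel)
    calls = [(r.key, r.mean_af) for r in results if r.call]
    ev = evaluate(
        calls,
        sim.truth.truth_pairs(),
        variant_tests=tested_variant_space(sim.panel),
    )
    return BenchmarkRun(seed=seed, eval_result=ev, n_called=len(calls))


def run_benchmark_suite(
    seeds: Sequence[int],
    sim_config: SimConfig | None = None,
    caller_config: CallerConfig | None = None,
) -> tuple[float, float, list[BenchmarkRun]]:
    """Mean sensitivity (%) and mean FP per 10k variant tests over seeds."""
    runs = [run_benchmark(s, sim_config, caller_config) for s in seeds]
    sens = float(np.mean([r.eval_result.sensitivity for r in runs]) * 100.0)
    fp10k = float(np.mean([r.eval_result.fp_per_10k for r in runs]))
    return sens, fp10k, runs
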