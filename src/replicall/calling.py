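"""Final call assembly.

Pipeline per candidate variant: exact NB enrichment p-value ->
Benjamini-Hochberg adjustment across the full tested variant space ->
direction check (sample normalized mean must exceed control) ->
strand-bias filter -> mean allele-frequency threshold. Every tested
variant is returned, called or not, with its rejection reasons, so the
result table doubles as a diagnostic dump.

The BH denominator defaults to the panel's full variant space
(base pairs x 4), not just the variants with observed support: the
correction is meant to span every hypothesis the panel could raise, and
unobserved variants (p = 1) cannot change the step-up result, so they
are folded in by inflating m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import CountMatrix, VariantKey, tested_variant_space
from .nbtest import (
    DispersionModel,
    NormalizationModel,
    estimate_dispersions,
    estimate_size_factors,
    nb_exact_pvalues,
)
from .pileup import PanelRegion

log = logging.getLogger(__name__)

# rejection reason codes (also used as VCF FILTER ids)
R_ADJP = "ADJ_P"
R_DIRECTION = "DIRECTION"
R_STRAND_BIAS = "STRAND_BIAS"
R_LOW_AF = "LOW_AF"
R_NO_AF = "NO_AF"


@dataclass
class CallerConfig:
    """Thresholds and modes for call assembly.

    ``alpha`` is the significance threshold on the BH-adjusted p-value;
    ``af_threshold`` the minimum mean allele frequency (default 0.05%,
    the bottom of the intended detection range); ``sbf_limit`` the
    maximum tolerated strand-bias-factor magnitude (exclusion is strictly
    above the limit); ``m_tests`` the BH denominator (defaults to the
    panel's bp x 4 variant space when a panel is given).
    """

    alpha: float = 0.05
    af_threshold: float = 5e-4
    sbf_limit: float = 5.0
    min_strand_support: int = 3
    m_tests: int | None = None
    min_base_quality: int = 30
    sided: str = "one_sided_enrichment"
    dispersion_sharing: str = "outlier"
    outlier_quantile: float = 0.99
    pseudo_mean: float = 0.5
    fallback_trend: tuple[float, float] = (0.1, 0.0)
    sample_consistency: bool = True
    max_enumeration: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sbf_limit <= 0:
            raise ValueError("sbf_limit must be positive")


@dataclass
class VariantTestResult:
    key: VariantKey
    p: float
    adj_p: float
    mean_af: float
    sbf: float
    sbf_magnitude: float
    k_sample: np.ndarray
    k_control: np.ndarray
    depth_sample: np.ndarray
    depth_control: np.ndarray
    n_rep_support: int
    call: bool
    reasons: tuple[str, ...]


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, returned in input order.

    ``m`` is the number of hypotheses in the family and may exceed the
    number of p-values actually computed (the remainder being implicit
    p = 1 tests); it must be at least ``len(pvalues)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m = {m} smaller than number of p-values {n}")
    if n == 0:
        return np.empty(0)
    order = np.lexsort((np.arange(n), p))  # stable in p
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def strand_bias_factor(fwd_af: float, rev_af: float) -> float:
    """Forward-strand AF over reverse-strand AF.

    Returns nan when both strands show no signal (the filter does not
    apply) and +/-inf when exactly one strand is silent.
    """
    for v in (fwd_af, rev_af):
        if not 0 <= v <= 1:
            raise ValueError("allele frequencies must be in [0, 1]")
    if fwd_af == 0 and rev_af == 0:
        return float("nan")
    if rev_af == 0:
        return float("inf")
    return fwd_af / rev_af


def sbf_magnitude(sbf: float) -> float:
    """max(SBF, 1/SBF): the deviation from 1 in either direction."""
    if np.isnan(sbf):
        return float("nan")
    if sbf == 0 or np.isinf(sbf):
        return float("inf")
    return max(sbf, 1.0 / sbf)


def mean_allele_frequency(counts: np.ndarray, depths: np.ndarray) -> float:
    """Unweighted mean of per-replicate allele frequencies.

    Replicates with zero depth at the position are skipped; nan when no
    replicate has coverage (the variant is then uncallable).
    """
    counts = np.asarray(counts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    covered = depths > 0
    if not covered.any():
        return float("nan")
    if not covered.all():
        log.warning("skipping %d zero-depth replicates in mean AF", (~covered).sum())
    return float((counts[covered] / depths[covered]).mean())


def call_variants(
    matrix: CountMatrix,
    cfg: CallerConfig | None = None,
    panel: Sequence[PanelRegion] | None = None,
) -> list[VariantTestResult]:
    """Run the full statistical caller on a count matrix."""
    cfg = cfg or CallerConfig()
    n = matrix.n_variants
    ns, nc = len(matrix.sample_labels), len(matrix.control_labels)
    if nc < 2:
        log.warning(
            "single control replicate: dispersion falls back to the trend "
            "prior alone; see the single-replicate mode documentation"
        )
    if ns == 1:
        log.info("single sample replicate mode: recurrent artifacts are still "
                 "suppressed, stochastic errors are not")
    m = cfg.m_tests if cfg.m_tests is not None else (
        tested_variant_space(panel) if panel is not None else n
    )
    if m < n:
        raise ValueError(
            f"BH denominator m = {m} smaller than the {n} tested variants"
        )
    if n == 0:
        return []

    norm = estimate_size_factors(
        matrix.position_depth_matrix(),
        labels=matrix.sample_labels + matrix.control_labels,
    )
    s = norm.size_factors
    s_A, s_B = s[:ns], s[ns:]
    S_A, S_B = float(s_A.sum()), float(s_B.sum())
    ssq_A, ssq_B = float(np.square(s_A).sum()), float(np.square(s_B).sum())

    sample_counts = matrix.sample_counts
    control_counts = matrix.control_counts
    disp = estimate_dispersions(
        control_counts,
        s_B,
        pseudo_mean=cfg.pseudo_mean,
        sharing_mode=cfg.dispersion_sharing,
        outlier_quantile=cfg.outlier_quantile,
        fallback_trend=cfg.fallback_trend,
        sample_counts=sample_counts if cfg.sample_consistency else None,
        sample_size_factors=s_A,
    )
    sample_depths = matrix.sample_depths
    control_depths = matrix.control_depths
    K_A = sample_counts.sum(axis=1)
    K_B = control_counts.sum(axis=1)
    T = K_A + K_B
    p = nb_exact_pvalues(
        K_A, T, disp.alpha, S_A, S_B, ssq_A, ssq_B,
        sided=cfg.sided, max_enumeration=cfg.max_enumeration,
    )
    adj_p = bh_adjust(p, m=m)

    mean_A = (sample_counts / s_A).mean(axis=1)
    mean_B = (control_counts / s_B).mean(axis=1)

    # strand AFs from counts pooled across sample replicates
    cf = matrix.sample_fwd.sum(axis=1)
    cr = matrix.sample_rev.sum(axis=1)
    df_ = matrix.sample_depth_fwd.sum(axis=1)
    dr = matrix.sample_depth_rev.sum(axis=1)

    results: list[VariantTestResult] = []
    for i, key in enumerate(matrix.variants):
        reasons: list[str] = []
        if adj_p[i] >= cfg.alpha:
            reasons.append(R_ADJP)
        if mean_A[i] <= mean_B[i]:
            reasons.append(R_DIRECTION)

        fwd_af = cf[i] / df_[i] if df_[i] > 0 else 0.0
        rev_af = cr[i] / dr[i] if dr[i] > 0 else 0.0
        sbf = strand_bias_factor(fwd_af, rev_af)
        mag = sbf_magnitude(sbf)
        if np.isnan(sbf):
            pass  # no signal on either strand: filter does not apply
        elif np.isinf(mag):
            supported = cf[i] if rev_af == 0 else cr[i]
            if supported >= cfg.min_strand_support:
                reasons.append(R_STRAND_BIAS)
        elif mag > cfg.sbf_limit:
            reasons.append(R_STRAND_BIAS)

        af = mean_allele_frequency(sample_counts[i], sample_depths[i])
        if np.isnan(af):
            reasons.append(R_NO_AF)
        elif af < cfg.af_threshold:
            reasons.append(R_LOW_AF)

        results.append(
            VariantTestResult(
                key=key,
                p=float(p[i]),
                adj_p=float(adj_p[i]),
                mean_af=af,
                sbf=sbf,
                sbf_magnitude=mag,
                k_sample=sample_counts[i],
                k_control=control_counts[i],
                depth_sample=sample_depths[i],
                depth_control=control_depths[i],
                n_rep_support=int((sample_counts[i] > 0).sum()),
                call=not reasons,
                reasons=tuple(reasons),
            )
        )
    log.info(
        "tested %d variants (m = %d): %d called",
        n, m, sum(r.call for r in results),
    )
    return results


def results_to_frame(results: Sequence[VariantTestResult]):
    """Flatten results into a DataFrame for the TSV report."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "contig": r.key.contig,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "vclass": r.key.vclass.value,
                "p": r.p,
                "adj_p": r.adj_p,
                "mean_af": r.mean_af,
                "sbf": r.sbf,
                "sbf_magnitude": r.sbf_magnitude,
                "n_rep_support": r.n_rep_support,
                "sample_counts": ",".join(map(str, r.k_sample)),
                "control_counts": ",".join(map(str, r.k_control)),
                "sample_depths": ",".join(map(str, r.depth_sample)),
                "control_depths": ",".join(map(str, r.depth_control)),
                "call": r.call,
                "reasons": ";".join(r.reasons) or "PASS",
            }
        )
    return pd.DataFrame(rows)
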