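"""Negative-binomial enrichment testing of sample vs. control counts.

The model follows the count-based differential framework used for NGS
count data: per-replicate counts k_j at a variant are negative binomial
with mean s_j * q (size factor times common rate) and variance
mu + alpha * mu^2. Under the null hypothesis that sample and control
replicates share one rate q, the pooled condition totals K_A and K_B are
compared with an exact conditional test: given the grand total
T = K_A + K_B, the probability of each split (a, T - a) is evaluated
under the two marginal NB laws and the tail containing the observation
is summed. In the Poisson limit (alpha = 0, equal size factors) this
reduces exactly to a binomial test on the split.

Dispersions are estimated from control replicates only: controls are
wild-type by construction, so a true variant in the sample cannot
inflate its own background variance and cost power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

_LOG_TINY = -745.0  # under this, exp() underflows float64


@dataclass
class NormalizationModel:
    """Median-of-ratios size factors, one per replicate (samples first)."""

    size_factors: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")


def estimate_size_factors(depth_matrix: np.ndarray, labels: Sequence[str] | None = None) -> NormalizationModel:
    """Size factors from a positions x replicates depth matrix.

    s_j = median over positions of depth_pj / geometric-mean_j(depth_pj),
    computed over positions covered (depth > 0) in every replicate. With
    identical depth profiles all s_j are exactly 1.
    """
    d = np.asarray(depth_matrix, dtype=float)
    if d.ndim != 2 or d.shape[1] < 1:
        raise ValueError("depth matrix must be positions x replicates")
    covered = (d > 0).all(axis=1)
    if not covered.any():
        raise ValueError("no position covered in all replicates")
    logd = np.log(d[covered])
    log_ratio = logd - logd.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_ratio, axis=0))
    return NormalizationModel(size_factors=s, labels=list(labels or []))


@dataclass
class DispersionModel:
    """Per-variant dispersions plus the fitted mean-dispersion trend.

    ``alpha_raw`` is the unclamped method-of-moments estimate (can be
    negative for sub-Poisson control counts), ``alpha_hat`` its value
    clamped at zero, ``mu`` the pooled normalized control mean. The
    trend alpha_trend(mu) = a0 + a1/mu is fit by non-negative least
    squares on the unclamped estimates so that pure sampling noise,
    which is symmetric around zero, does not bias the trend upward.

    ``alpha`` is the dispersion the test uses. Two sharing modes:

    - ``"outlier"`` (default): the trend value, escalated to
      max(alpha_hat, trend) only where the control variance exceeds the
      ``outlier_quantile`` chi-square quantile of its null expectation
      under the trend. Variants whose replicate scatter is genuinely
      excessive are tested conservatively; everyone else is not punished
      for the sampling noise of a handful of low counts.
    - ``"maximum"``: max(alpha_hat, trend) everywhere; uniformly
      conservative, at a substantial cost in power with few replicates.
    """

    alpha_raw: np.ndarray
    alpha_hat: np.ndarray
    mu: np.ndarray
    a0: float
    a1: float
    alpha: np.ndarray
    outlier: np.ndarray
    pseudo_mean: float
    sharing_mode: str

    def trend(self, mu: np.ndarray | float) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        safe = np.where(mu > 0, mu, self.pseudo_mean)
        return self.a0 + self.a1 / safe


def fit_dispersion_trend(alpha_raw: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """NNLS fit of alpha ~ a0 + a1/mu over variants with mu > 0."""
    mask = mu > 0
    if mask.sum() < 2:
        raise ValueError("need >=2 variants with positive control mean to fit trend")
    design = np.column_stack([np.ones(mask.sum()), 1.0 / mu[mask]])
    coef, _ = optimize.nnls(design, np.clip(alpha_raw[mask], -1e6, 1e6))
    return float(coef[0]), float(coef[1])


def estimate_dispersions(
    control_counts: np.ndarray,
    control_size_factors: np.ndarray,
    pseudo_mean: float = 0.5,
    sharing_mode: str = "outlier",
    outlier_quantile: float = 0.99,
    fallback_trend: tuple[float, float] = (0.1, 0.0),
    sample_counts: np.ndarray | None = None,
    sample_size_factors: np.ndarray | None = None,
) -> DispersionModel:
    """Method-of-moments dispersions from control replicates.

    For each variant, normalized counts z_j = k_j / s_j over controls
    give mu = mean(z) and w = sample variance(z); the shot-noise
    corrected moment estimate is (w - xi * mu) / mu^2 with
    xi = mean_j(1 / s_j). With fewer than 2 control replicates no
    variance can be formed and the trend prior alone, with
    ``fallback_trend`` coefficients, is used (single-replicate mode).

    When ``sample_counts`` (and its size factors) are given, the SAMPLE
    replicates' scatter is screened with the same chi-square outlier
    rule against its own mean, and variants whose sample replicates
    disagree far beyond shot noise have the sample-side empirical
    dispersion folded into the final alpha. This is what eliminates
    stochastic errors — signals present in one library but not its
    sibling replicates — rather than merely recurrent artifacts, which
    the control background already covers.
    """
    k = np.asarray(control_counts, dtype=float)
    s = np.asarray(control_size_factors, dtype=float)
    if k.ndim != 2:
        raise ValueError("control counts must be variants x replicates")
    n_var, n_ctrl = k.shape
    if sharing_mode not in ("outlier", "maximum"):
        raise ValueError(f"unknown sharing mode {sharing_mode!r}")
    z = k / s
    mu = z.mean(axis=1)
    if n_ctrl < 2:
        a0, a1 = fallback_trend
        alpha_raw = np.zeros(n_var)
        alpha_hat = np.zeros(n_var)
        model = DispersionModel(
            alpha_raw=alpha_raw, alpha_hat=alpha_hat, mu=mu, a0=a0, a1=a1,
            alpha=np.zeros(n_var), outlier=np.zeros(n_var, bool),
            pseudo_mean=pseudo_mean, sharing_mode=sharing_mode,
        )
        model.alpha = model.trend(mu)
        return model
    xi = float(np.mean(1.0 / s))
    w = z.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, (w - xi * mu) / np.square(mu), 0.0)
    alpha_hat = np.clip(alpha_raw, 0.0, None)
    try:
        a0, a1 = fit_dispersion_trend(alpha_raw, mu)
    except ValueError:
        a0, a1 = fallback_trend
    trend = a0 + a1 / np.where(mu > 0, mu, pseudo_mean)
    # null expectation of the control variance under the trend dispersion
    v_null = xi * mu + trend * np.square(mu)
    crit = stats.chi2.ppf(outlier_quantile, df=n_ctrl - 1) / (n_ctrl - 1)
    outlier = (mu > 0) & (w > v_null * crit)
    if sharing_mode == "maximum":
        alpha = np.maximum(alpha_hat, trend)
    else:
        alpha = np.where(outlier, np.maximum(alpha_hat, trend), trend)
    if sample_counts is not None and np.shape(sample_counts)[1] >= 2:
        ks = np.asarray(sample_counts, dtype=float)
        ss = np.asarray(sample_size_factors, dtype=float)
        zs = ks / ss
        mu_s = zs.mean(axis=1)
        w_s = zs.var(axis=1, ddof=1)
        xi_s = float(np.mean(1.0 / ss))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_s = np.where(mu_s > 0, (w_s - xi_s * mu_s) / np.square(mu_s), 0.0)
        v_null_s = xi_s * mu_s + trend * np.square(mu_s)
        crit_s = stats.chi2.ppf(outlier_quantile, df=ks.shape[1] - 1) / (ks.shape[1] - 1)
        sample_outlier = (mu_s > 0) & (w_s > v_null_s * crit_s)
        alpha = np.where(sample_outlier, np.maximum(alpha, np.clip(alpha_s, 0, None)), alpha)
        outlier = outlier | sample_outlier
    return DispersionModel(
        alpha_raw=alpha_raw, alpha_hat=alpha_hat, mu=mu, a0=a0, a1=a1,
        alpha=alpha, outlier=outlier, pseudo_mean=pseudo_mean,
        sharing_mode=sharing_mode,
    )


@dataclass
class TestInput:
    """Pooled per-condition evidence for one variant."""

    k_sample: np.ndarray  # per sample replicate, strands pooled
    k_control: np.ndarray
    s_sample: np.ndarray  # size factors
    s_control: np.ndarray
    alpha: float

    @property
    def K_A(self) -> int:
        return int(self.k_sample.sum())

    @property
    def K_B(self) -> int:
        return int(self.k_control.sum())

    @property
    def T(self) -> int:
        return self.K_A + self.K_B


def pooled_condition_counts(matrix, i: int, norm: NormalizationModel, alpha: float) -> TestInput:
    """Extract one matrix row as a TestInput (strands summed)."""
    ns = len(matrix.sample_labels)
    s = norm.size_factors
    return TestInput(
        k_sample=matrix.sample_counts[i],
        k_control=matrix.control_counts[i],
        s_sample=s[:ns],
        s_control=s[ns:],
        alpha=alpha,
    )


def _nb_logpmf(k: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log pmf of NB parameterized by mean and variance; Poisson when var==mean."""
    k = np.asarray(k, dtype=float)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), k.shape)
    var = np.broadcast_to(np.asarray(var, dtype=float), k.shape)
    out = np.empty_like(k)
    over = var > mean * (1 + 1e-12)
    if over.any():
        m, v = mean[over], var[over]
        r = m * m / (v - m)
        p = r / (r + m)
        out[over] = stats.nbinom.logpmf(k[over], r, p)
    if (~over).any():
        out[~over] = stats.poisson.logpmf(k[~over], mean[~over])
    return out


def nb_exact_pvalues(
    K_A: np.ndarray,
    T: np.ndarray,
    alpha: np.ndarray,
    S_A: float,
    S_B: float,
    ssq_A: float,
    ssq_B: float,
    sided: str = "one_sided_enrichment",
    max_enumeration: int = 10_000,
) -> np.ndarray:
    """Vectorized exact conditional NB test over many variants.

    For each variant the common rate under the null is q = T / (S_A +
    S_B); the condition totals are NB with means q*S_A, q*S_B and
    variances mean + alpha * (sum of squared size factors) * q^2. All
    T + 1 splits are enumerated in log space (flattened across variants
    for speed); beyond ``max_enumeration`` total counts a normal
    approximation of the conditional law is used.
    """
    if sided not in ("one_sided_enrichment", "two_sided"):
        raise ValueError(f"unknown sidedness {sided!r}")
    K_A = np.asarray(K_A, dtype=np.int64)
    T = np.asarray(T, dtype=np.int64)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(K_A < 0) or np.any(T < K_A):
        raise ValueError("counts must satisfy 0 <= K_A <= T")
    if np.any(alpha < 0):
        raise ValueError("dispersion must be non-negative")
    n = len(T)
    p_out = np.ones(n)

    S = S_A + S_B
    q = T / S
    mA, mB = q * S_A, q * S_B
    vA = mA + alpha * ssq_A * q * q
    vB = mB + alpha * ssq_B * q * q

    enum = (T > 0) & (T <= max_enumeration)
    if enum.any():
        idx = np.flatnonzero(enum)
        sizes = T[idx] + 1
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        total = int(sizes.sum())
        rep = np.repeat(np.arange(len(idx)), sizes)
        a = np.arange(total) - np.repeat(starts, sizes)
        vi = idx[rep]
        lp = _nb_logpmf(a, mA[vi], vA[vi]) + _nb_logpmf(T[vi] - a, mB[vi], vB[vi])
        # segmented log-sum-exp over all splits
        seg_max = np.maximum.reduceat(lp, starts)
        ex = np.exp(np.maximum(lp - seg_max[rep], _LOG_TINY))
        denom = np.add.reduceat(ex, starts)
        if sided == "one_sided_enrichment":
            mask = a >= K_A[vi]
        else:
            lp_obs = lp[starts + K_A[idx]]
            mask = lp <= lp_obs[rep] + 1e-12
        numer = np.add.reduceat(np.where(mask, ex, 0.0), starts)
        p_out[idx] = np.clip(numer / denom, 0.0, 1.0)

    big = T > max_enumeration
    if big.any():
        # conditional on T the expected sample share is exactly mA because
        # mA + mB == T; only the conditional variance needs the NB laws
        sd = np.sqrt(vA[big] * vB[big] / (vA[big] + vB[big]))
        zhi = (K_A[big] - 0.5 - mA[big]) / sd
        upper = stats.norm.sf(zhi)
        if sided == "one_sided_enrichment":
            p_out[big] = upper
        else:
            zlo = (K_A[big] + 0.5 - mA[big]) / sd
            lower = stats.norm.cdf(zlo)
            p_out[big] = np.clip(2.0 * np.minimum(upper, lower), 0.0, 1.0)
    return p_out


def nb_exact_pvalue(t: TestInput, sided: str = "one_sided_enrichment",
                    max_enumeration: int = 10_000) -> float:
    """Exact conditional NB p-value for a single variant."""
    S_A, S_B = float(t.s_sample.sum()), float(t.s_control.sum())
    ssq_A = float(np.square(t.s_sample).sum())
    ssq_B = float(np.square(t.s_control).sum())
    return float(
        nb_exact_pvalues(
            np.array([t.K_A]), np.array([t.T]), np.array([t.alpha]),
            S_A, S_B, ssq_A, ssq_B, sided=sided, max_enumeration=max_enumeration,
        )[0]
    )
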