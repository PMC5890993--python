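"""Synthetic replicate data with a known error landscape.

The generator emulates the two error classes that dominate deep targeted
sequencing of wild-type DNA:

- **recurrent artifacts**: error-prone loci whose elevated rate is a
  property of the locus, shared by every replicate of both conditions
  (library chemistry and sequencing context, not the sample);
- **stochastic errors**: polymerase/sequencing errors that populate an
  individual library at random, modeled as rare per-variant,
  per-replicate rate bursts on top of a uniform base error rate.

True variants are spiked at specified allele frequencies through an
explicit input-copy model: each sample replicate receives a Poisson
number of mutant template copies given the DNA input mass (3 pg per
haploid copy, so 10 ng of input is ~3333 copies of each allele), which
is what makes sub-0.1% AF detection input-limited rather than
noise-limited.

Every count is drawn per strand from the position's simulated depth, so
matrices, mpileup text, truth VCFs and panels round-trip exactly through
the parser and matrix builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TextIO

import numpy as np

from .matrix import CountMatrix, VariantClass, VariantKey
from .pileup import PanelRegion

#: mass of one haploid human genome copy, in nanograms
HAPLOID_GENOME_NG = 0.003

_ALT_ORDER = {b: i for i, b in enumerate("ACGT")}


def copies_per_replicate(input_ng: float, haploid_ng: float = HAPLOID_GENOME_NG) -> float:
    """Haploid template copies available to one replicate's library."""
    if input_ng <= 0:
        raise ValueError("input mass must be positive")
    return input_ng / haploid_ng


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the intended study conditions.

    Depth is near 5000x with negative-binomial noise, a shared
    per-position amplicon-efficiency factor and a per-replicate library
    yield factor. Stochastic error bursts multiply a variant's rate in
    one replicate by a log-normal factor (median 12, so a burst over the
    1e-4 base rate lands near 0.12% AF: stochastic errors dominate below
    ~0.5% AF). Artifact rates are log-normal across loci, clipped to
    [1e-4, 2e-2].
    """

    panel_bp: int = 6250
    contig: str = "sim1"
    n_sample: int = 4
    n_control: int = 4
    depth: int = 5000
    depth_dispersion: float = 0.002
    rep_depth_sd: float = 0.1
    pos_depth_sd: float = 0.3
    e0_snv: float = 1e-4
    e0_indel: float = 2e-5
    artifact_fraction: float = 0.01
    artifact_meanlog: float = math.log(8e-4)
    artifact_sdlog: float = 1.2
    artifact_rate_min: float = 1e-4
    artifact_rate_max: float = 2e-2
    burst_prob: float = 1e-3
    burst_meanlog: float = math.log(12.0)
    burst_sdlog: float = 0.4
    input_ng: float = 10.0
    truth: tuple[tuple[VariantKey, float], ...] = ()
    n_truth: int = 0
    truth_af_low: float = 5e-4
    truth_af_high: float = 1e-2
    truth_indel_fraction: float = 0.1
    min_supporting_reads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_bp <= 0 or self.depth <= 0:
            raise ValueError("panel_bp and depth must be positive")
        if not 0 <= self.artifact_fraction <= 1:
            raise ValueError("artifact_fraction must be in [0, 1]")
        for r in (self.e0_snv, self.e0_indel, self.burst_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        for _, af in self.truth:
            if af > 0.5:
                raise ValueError(
                    f"truth AF {af} > 0.5 is outside the intended ultralow "
                    "frequency regime"
                )
            if af <= 0:
                raise ValueError("truth AF must be positive")

    @property
    def copies_per_replicate(self) -> float:
        return copies_per_replicate(self.input_ng)


@dataclass
class TruthVariant:
    key: VariantKey
    af: float
    copies: np.ndarray  # mutant template copies per sample replicate
    realized_af: np.ndarray


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    variants: list[TruthVariant]
    artifacts: list[tuple[VariantKey, float]]
    seed: int
    copies_per_replicate: float

    def truth_pairs(self) -> list[tuple[VariantKey, float]]:
        return [(t.key, t.af) for t in self.variants]


@dataclass
class SimResult:
    """Simulated matrix, ground truth and raw per-site arrays.

    The raw arrays cover every variant site of the panel (4 per bp, in
    canonical order) and every replicate, so mpileup text can be emitted
    for any replicate; ``matrix`` holds the sample-supported subset in
    the same form :func:`replicall.matrix.build_matrix` would build.
    """

    config: SimConfig
    matrix: CountMatrix
    truth: SimTruth
    reference: str  # panel sequence plus one trailing base for deletions
    site_keys: list[VariantKey]
    counts_fwd: np.ndarray  # (n_sites, n_reps) samples first
    counts_rev: np.ndarray
    depth_fwd: np.ndarray  # (panel_bp, n_reps)
    depth_rev: np.ndarray

    @property
    def panel(self) -> list[PanelRegion]:
        return [PanelRegion(self.config.contig, 1, self.config.panel_bp)]


def _site_keys(reference: str, contig: str, panel_bp: int) -> list[VariantKey]:
    """Canonical site order: per position, 3 alt bases (sorted) then '-1'."""
    keys: list[VariantKey] = []
    for pos in range(1, panel_bp + 1):
        ref = reference[pos - 1]
        for alt in "ACGT":
            if alt != ref:
                keys.append(VariantKey(contig, pos, ref, alt, VariantClass.SNV))
        keys.append(VariantKey(contig, pos, ref, "-1", VariantClass.DEL))
    return keys


def make_truth_set(
    reference: str,
    contig: str,
    panel_bp: int,
    n: int,
    af_low: float,
    af_high: float,
    rng: np.random.Generator,
    indel_fraction: float = 0.1,
) -> tuple[tuple[VariantKey, float], ...]:
    """Spike set with AFs evenly spaced from af_low to af_high.

    Positions are distinct and uniform over the panel; a fixed fraction
    of the variants are single-base deletions, the rest SNVs with a
    random non-reference alternative base.
    """
    if n > panel_bp:
        raise ValueError("more truth variants than panel positions")
    afs = np.linspace(af_low, af_high, n)
    positions = rng.choice(panel_bp, size=n, replace=False) + 1
    n_indel = int(round(indel_fraction * n))
    out = []
    for i, (pos, af) in enumerate(zip(positions, afs)):
        ref = reference[pos - 1]
        if i < n_indel:
            key = VariantKey(contig, int(pos), ref, "-1", VariantClass.DEL)
        else:
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            key = VariantKey(contig, int(pos), ref, alt, VariantClass.SNV)
        out.append((key, float(af)))
    return tuple(out)


def _draw_depths(cfg: SimConfig, rng: np.random.Generator, n_reps: int) -> np.ndarray:
    rep_f = np.exp(rng.normal(0.0, cfg.rep_depth_sd, size=n_reps))
    pos_f = np.exp(rng.normal(0.0, cfg.pos_depth_sd, size=cfg.panel_bp))
    mean = cfg.depth * np.outer(pos_f, rep_f)
    if cfg.depth_dispersion > 0:
        r = 1.0 / cfg.depth_dispersion
        p = r / (r + mean)
        d = rng.negative_binomial(r, p)
    else:
        d = np.rint(mean).astype(np.int64)
    return np.maximum(d, 1)


def simulate_counts(cfg: SimConfig) -> SimResult:
    """Draw one full replicate experiment from the generative model."""
    rng = np.random.default_rng(cfg.seed)
    L, R = cfg.panel_bp, cfg.n_sample + cfg.n_control
    # one trailing base so a deletion at the last panel position has a target
    reference = "".join(rng.choice(list("ACGT"), size=L + 1))
    truth_spec = cfg.truth
    if not truth_spec and cfg.n_truth > 0:
        truth_spec = make_truth_set(
            reference, cfg.contig, L, cfg.n_truth,
            cfg.truth_af_low, cfg.truth_af_high, rng,
            indel_fraction=cfg.truth_indel_fraction,
        )
    elif truth_spec:
        # honor explicit truth keys: force the reference base at their sites
        ref_list = list(reference)
        for key, _ in truth_spec:
            if not 1 <= key.pos <= L:
                raise ValueError(f"truth variant at {key.pos} outside panel")
            ref_list[key.pos - 1] = key.ref
        reference = "".join(ref_list)

    site_keys = _site_keys(reference, cfg.contig, L)
    site_index = {k: i for i, k in enumerate(site_keys)}
    n_sites = len(site_keys)

    is_indel = np.zeros(n_sites, dtype=bool)
    is_indel[3::4] = True
    rates = np.where(is_indel, cfg.e0_indel, cfg.e0_snv).astype(float)

    truth_idx = np.array(
        sorted(site_index[k] for k, _ in truth_spec), dtype=int
    )
    # recurrent artifacts: locus-specific rates shared by ALL replicates,
    # disjoint from spiked truth by construction
    n_art = int(round(cfg.artifact_fraction * n_sites))
    eligible = np.setdiff1d(np.arange(n_sites), truth_idx, assume_unique=True)
    art_idx = np.sort(rng.choice(eligible, size=n_art, replace=False)) if n_art else np.empty(0, int)
    art_rates = np.clip(
        np.exp(rng.normal(cfg.artifact_meanlog, cfg.artifact_sdlog, size=n_art)),
        cfg.artifact_rate_min,
        cfg.artifact_rate_max,
    )
    rates[art_idx] = art_rates

    # per-replicate stochastic bursts (both conditions)
    rate_matrix = np.repeat(rates[:, None], R, axis=1)
    burst_mask = rng.random((n_sites, R)) < cfg.burst_prob
    n_burst = int(burst_mask.sum())
    if n_burst:
        factors = np.exp(rng.normal(cfg.burst_meanlog, cfg.burst_sdlog, size=n_burst))
        rate_matrix[burst_mask] *= factors

    # spiked truth: Poisson input copies per sample replicate
    copies = cfg.copies_per_replicate
    truth_variants: list[TruthVariant] = []
    for key, af in truth_spec:
        c = rng.poisson(copies * af, size=cfg.n_sample)
        realized = c / copies
        rate_matrix[site_index[key], : cfg.n_sample] += realized
        truth_variants.append(TruthVariant(key=key, af=af, copies=c, realized_af=realized))

    depth = _draw_depths(cfg, rng, R)
    depth_fwd = rng.binomial(depth, 0.5)
    depth_rev = depth - depth_fwd

    pos_of_site = np.repeat(np.arange(L), 4)
    r = np.clip(rate_matrix, 0.0, 1.0)
    counts_fwd = rng.binomial(depth_fwd[pos_of_site], r)
    counts_rev = rng.binomial(depth_rev[pos_of_site], r)

    # guard the count <= depth invariant at each (position, strand):
    # SNV alt reads displace reference reads, so their sum is capped by
    # depth (deletion tokens ride on anchors and do not consume depth)
    for counts, dstr in ((counts_fwd, depth_fwd), (counts_rev, depth_rev)):
        snv = counts.reshape(L, 4, R)[:, :3, :]
        excess = snv.sum(axis=1) - dstr
        over = excess > 0
        if over.any():  # astronomically rare at realistic rates
            for p_i, j in zip(*np.nonzero(over)):
                need = excess[p_i, j]
                for a in range(3):
                    take = min(need, snv[p_i, a, j])
                    snv[p_i, a, j] -= take
                    need -= take
                    if need == 0:
                        break
        # deletion support cannot exceed available ref anchors
        dele = counts.reshape(L, 4, R)[:, 3, :]
        anchors = dstr - snv.sum(axis=1)
        np.minimum(dele, anchors, out=dele)

    truth = SimTruth(
        variants=truth_variants,
        artifacts=[(site_keys[i], float(rates[i])) for i in art_idx],
        seed=cfg.seed,
        copies_per_replicate=copies,
    )

    keep = counts_fwd[:, : cfg.n_sample].sum(axis=1) + counts_rev[:, : cfg.n_sample].sum(axis=1)
    keep_idx = np.flatnonzero(keep >= cfg.min_supporting_reads)
    pos_idx = pos_of_site[keep_idx]
    ns = cfg.n_sample
    matrix = CountMatrix(
        variants=[site_keys[i] for i in keep_idx],
        sample_labels=[f"sample_{j+1}" for j in range(cfg.n_sample)],
        control_labels=[f"control_{j+1}" for j in range(cfg.n_control)],
        sample_fwd=counts_fwd[keep_idx, :ns],
        sample_rev=counts_rev[keep_idx, :ns],
        control_fwd=counts_fwd[keep_idx, ns:],
        control_rev=counts_rev[keep_idx, ns:],
        sample_depth_fwd=depth_fwd[pos_idx, :ns],
        sample_depth_rev=depth_rev[pos_idx, :ns],
        control_depth_fwd=depth_fwd[pos_idx, ns:],
        control_depth_rev=depth_rev[pos_idx, ns:],
    )
    return SimResult(
        config=cfg,
        matrix=matrix,
        truth=truth,
        reference=reference,
        site_keys=site_keys,
        counts_fwd=counts_fwd,
        counts_rev=counts_rev,
        depth_fwd=depth_fwd,
        depth_rev=depth_rev,
    )


DEFAULT_QUALITY_CHAR = "F"  # Phred+33 for Q37


def emit_mpileup(
    sim: SimResult,
    condition: str,
    rep_index: int,
    out: TextIO,
    quality_char: str = DEFAULT_QUALITY_CHAR,
) -> None:
    """Write one replicate of a simulation as samtools mpileup text.

    Output parses back (at any quality threshold at or below the emitted
    quality) to exactly the simulated per-strand counts and depths.
    Deletion-supporting reads are represented as their anchor token on a
    reference read; spanning ``*`` placeholders at downstream positions
    are not emitted, so depth at each position is exactly the simulated
    depth.
    """
    if condition not in ("sample", "control"):
        raise ValueError("condition must be 'sample' or 'control'")
    j = rep_index if condition == "sample" else sim.config.n_sample + rep_index
    cfg = sim.config
    for pos in range(1, cfg.panel_bp + 1):
        base0 = (pos - 1) * 4
        ref = sim.reference[pos - 1]
        alts = [k.alt for k in sim.site_keys[base0 : base0 + 3]]
        df_, dr = int(sim.depth_fwd[pos - 1, j]), int(sim.depth_rev[pos - 1, j])
        snv_f = [int(sim.counts_fwd[base0 + a, j]) for a in range(3)]
        snv_r = [int(sim.counts_rev[base0 + a, j]) for a in range(3)]
        del_f = int(sim.counts_fwd[base0 + 3, j])
        del_r = int(sim.counts_rev[base0 + 3, j])
        del_token = f"-1{sim.reference[pos]}"
        ref_f = df_ - sum(snv_f)
        ref_r = dr - sum(snv_r)
        parts = [("." + del_token) * del_f, "." * (ref_f - del_f)]
        parts += [alt * c for alt, c in zip(alts, snv_f)]
        parts += [("," + del_token.lower()) * del_r, "," * (ref_r - del_r)]
        parts += [alt.lower() * c for alt, c in zip(alts, snv_r)]
        bases = "".join(parts)
        out.write(
            f"{cfg.contig}\t{pos}\t{ref}\t{df_ + dr}\t{bases}\t"
            f"{quality_char * (df_ + dr)}\n"
        )


def write_truth_tsv(truth: SimTruth, out: TextIO) -> None:
    """Ground truth as TSV: spiked variants then artifact loci."""
    out.write("record\tcontig\tpos\tref\talt\tvclass\taf_or_rate\tcopies\trealized_af\n")
    for t in truth.variants:
        out.write(
            f"truth\t{t.key.contig}\t{t.key.pos}\t{t.key.ref}\t{t.key.alt}\t"
            f"{t.key.vclass.value}\t{t.af:.6g}\t"
            f"{','.join(map(str, t.copies))}\t"
            f"{','.join(f'{a:.6g}' for a in t.realized_af)}\n"
        )
    for key, rate in truth.artifacts:
        out.write(
            f"artifact\t{key.contig}\t{key.pos}\t{key.ref}\t{key.alt}\t"
            f"{key.vclass.value}\t{rate:.6g}\t\t\n"
        )
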