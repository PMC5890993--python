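# Methods

## Problem setting

Deep targeted sequencing (amplicon panels at ~5,000x) of cell-free or
genomic DNA is used to find somatic variants at allele frequencies (AF)
between 0.05% and ~1%. At these frequencies the variant signal is of the
same order as the assay's error floor, and the errors fall into two
classes with very different statistics:

- **recurrent artifacts** — error-prone loci whose elevated miscall rate
  is a reproducible property of the locus (context-dependent polymerase
  or sequencing chemistry errors). They recur in every library made with
  the same chemistry, wild-type or not.
- **stochastic errors** — polymerase errors that enter an individual
  library during amplification and are then faithfully sequenced. They
  appear at random positions, in one library but not its siblings, and
  dominate the false-positive landscape below ~0.5% AF.

`replicall` suppresses both by exploiting technical replication on both
sides of the comparison: N sample replicates against M wild-type control
replicates, library-prepped and sequenced the same way. Recurrent
artifacts appear equally in controls and cancel in the test; stochastic
errors betray themselves by inconsistency across the sample replicates.

## Count model and the enrichment test

For each candidate variant i (a (position, alt allele) pair with at
least one supporting read in some sample replicate) the data are the
strand-split supporting read counts k_ij per replicate j, plus the
position's depth. Counts are modeled as negative binomial,

    k_ij ~ NB(mean = s_j * q_i,  var = mu + alpha_i * mu^2),

where s_j is a per-replicate size factor (median-of-ratios over the
panel's per-position depths, the standard normalization for NGS count
matrices) and alpha_i the variant's dispersion. Under the null
hypothesis both conditions share one rate q_i.

The test conditions on the total T = K_A + K_B of the pooled condition
sums (K_A over sample replicates, K_B over controls). With
q = T / (S_A + S_B), S_c the summed size factors of condition c, the
marginal laws are

    K_A ~ NB(mean m_A = q * S_A, var m_A + alpha * (sum_j s_j^2) * q^2),

and analogously for K_B. Every split (a, T − a) is enumerated, its
probability P_A(a) P_B(T − a) accumulated in log space, and the
one-sided enrichment p-value is the normalized mass of splits with
a >= K_A (two-sided: all splits at most as probable as the observation).
In the Poisson limit (alpha = 0) this reduces exactly to a binomial test
on the split with success probability S_A / (S_A + S_B); the test suite
pins both this closed form and a brute-force enumeration oracle to
1e-10.

One-sided testing is the default: the calling hypothesis is directional
(a mutant allele adds reads to the sample side only), and the direction
(sample normalized mean > control normalized mean) is additionally
enforced before any call.

Numerical choices: all pmf accumulation happens in log space with a
segmented log-sum-exp, flattened across variants so a whole matrix is
tested in one vectorized pass. Enumeration is capped at T = 10,000
(configurable); beyond it a normal approximation of the conditional law
is used — because m_A + m_B = T exactly, only the conditional variance
v_A v_B / (v_A + v_B) is approximate, and totals that large belong to
germline-level variants that are called under any approximation.
Two-sided ties are included with a 1e-12 log-space tolerance. T = 0
yields p = 1.

## Dispersion estimation

Per-variant dispersions are method-of-moments estimates from the control
replicates (wild-type by construction): with normalized counts
z_j = k_j / s_j, mu = mean(z), w = var(z, ddof=1) and the shot-noise
correction xi = mean(1/s_j),

    alpha_raw = (w − xi * mu) / mu^2,   alpha_hat = max(alpha_raw, 0).

A mean–dispersion trend alpha(mu) = a0 + a1/mu is fit by non-negative
least squares **on the unclamped estimates**. This matters: at the
means typical of error counts (fractions of a read to a few reads per
replicate) the moment estimator's sampling noise is an order of
magnitude larger than any real dispersion, and it is symmetric around
zero — fitting on zero-clamped values would push the trend up by the
clamp bias alone and the test would pay for it in power everywhere.

The dispersion used by the test is, by default (`sharing_mode=
"outlier"`), the trend value — escalated to max(alpha_hat, trend) only
where the observed control variance exceeds the 99% chi-square quantile
of its null expectation under the trend. Variants whose replicate
scatter is genuinely pathological are therefore tested conservatively,
while everyone else is not punished for the noise of a 4-replicate
variance estimate. A uniformly conservative `"maximum"` mode
(always max(alpha_hat, trend)) is available; with few replicates it
costs substantial sensitivity because single aberrant control patterns
(e.g. counts 2,0,0,0 at mean 0.5 imply alpha_hat = 2) veto real variants.

**Sample-replicate consistency.** The same chi-square screen is applied
to the sample replicates against their own mean (`sample_consistency`,
default on). When the sample-side scatter is far beyond shot noise —
the signature of a stochastic error living in one library — the
sample-side empirical dispersion is folded into the test's alpha. This
is the mechanism that eliminates stochastic errors: a burst of 13 reads
in one of four replicates (with 0–1 reads in the others) is
overdispersion, not enrichment, and the widened null absorbs it. A true
variant's replicates agree to within Poisson input-copy noise and are
left untouched. With a single sample replicate no consistency
information exists; the caller still removes recurrent artifacts (the
control background) but, by design, cannot remove stochastic errors —
which is exactly the observed single-replicate behavior the replicate
trend test pins down.

With fewer than two control replicates no variance can be formed and a
flat weakly informative prior alpha = 0.1 (`fallback_trend = (0.1, 0)`)
is used; the same prior backstops degenerate matrices where the trend
cannot be fit. Variants with zero control support evaluate the trend at
a pseudo-mean of 0.5 normalized counts (roughly the background error
mean at 5,000x).

## Multiple testing and filters

Raw p-values are Benjamini–Hochberg adjusted with the family size m set
to the panel's **full variant space**, panel bp x 4 (3 possible SNVs
plus 1 indel test per base), not merely the variants with observed
support: the correction must span every hypothesis the panel could have
raised. Unobserved variants carry p = 1 and cannot change the step-up
result, so inflating m implements this exactly.

A call requires all of:

| check | default | notes |
|---|---|---|
| adjusted p < alpha | 0.05 | significance on the BH-adjusted p-value |
| mean AF >= af_threshold | 0.0005 | unweighted mean of per-replicate count/depth over sample replicates |
| SBF magnitude <= sbf_limit | 5 | SBF = fwd AF / rev AF from counts pooled across sample replicates; magnitude = max(SBF, 1/SBF); exclusion strictly above the limit; a single silent strand is infinite bias only when the loud strand has >= `min_strand_support` (3) reads |
| direction | — | sample normalized mean strictly above control |

Strand AFs are pooled across sample replicates before the ratio: at
ultralow AF the per-replicate strand counts are too sparse to ratio
individually. Thresholds are configuration, not constants — the right
operating point depends on panel size and the desired limit of
detection. All tested variants are returned with rejection reasons
(also written as VCF FILTER codes with `--emit-all`).

## Synthetic data generator

The simulator draws, per replicate and position, a depth
NB(mean = depth x position factor x replicate factor, dispersion 0.002),
with log-normal position factors (sd 0.3, shared across replicates —
amplicon efficiency) and replicate factors (sd 0.1 — library yield),
split binomially between strands. Per variant site (4 per bp: 3 SNV
alts + a 1-bp deletion):

- base error rates e0 = 1e-4 per SNV per read and 2e-5 per indel;
- **artifacts**: 1% of sites get a locus rate drawn log-normal
  (median 8e-4, sdlog 1.2, clipped to [1e-4, 2e-2]) shared by every
  replicate of both conditions — that sharing is the definition of
  "recurrent";
- **stochastic bursts**: independently per variant and replicate, with
  probability 1e-3 the rate is multiplied by a log-normal factor
  (median 12, sdlog 0.4), so bursts over the base rate land near 0.1%
  AF and dominate below ~0.5% — the qualitative shape of the stochastic
  error class;
- **spiked truth**: each sample replicate receives C_j ~ Poisson(copies
  x AF) mutant template copies, copies = input_ng / 3 pg (10 ng ->
  ~3333 haploid copies), and the realized per-replicate AF C_j / copies
  adds to the site's rate in sample replicates only. This reproduces
  the input-copy ceiling: at 0.05% AF and 10 ng, all four replicates
  carry a mutant copy only (1 − e^-1.67)^4 ≈ 43% of the time, so
  sub-0.1% sensitivity is input-limited, not noise-limited, and
  recovers when input is raised to 20 ng.

Counts are binomial per strand given depth and rate. Emitted mpileup
text (uniform Q37) parses back to exactly the simulated counts; the
only simplification is that deletion-spanning `*` placeholders are not
emitted at downstream positions (the parser accepts them in real data).

What the generator does **not** emulate, and hence what passing tests do
not establish for real data: sequence-context-specific error spectra,
strand-biased artifacts (simulated errors are strand-symmetric, so the
SBF filter is exercised by construction tests, not by the benchmark),
mapping/alignment artifacts around indels, UMI structure, and
GC-dependent coverage waves. Real-panel thresholds should be tuned on
real control replicates.

## Standard benchmark and problem sizes

The package's reference benchmark (also recomputed by
`scripts/acceptance.py`) simulates a 6,250 bp panel — 25,000 variant
tests — at 5,000x with 4 sample + 4 control replicates, 20 truth
variants with AFs evenly spaced from 0.05% to 1% at 20 ng input per
replicate, default error landscape, scored over 10 seeds. Evenly spaced
AFs mirror how analytical spike-in dilution series are built. Panel and
seed counts are chosen so the whole benchmark runs in seconds on one
core while every stage (background estimation, testing at ~21,000
candidate sites per seed, BH across 25,000 hypotheses) is exercised at
realistic per-site statistics; the calibration tests use a 2,500 bp
(10,000-test) null panel and a 1,000 bp panel for the replicate-number
trend over 25 seeds.

Typical results at the default configuration: mean sensitivity 91–95%
(the misses concentrate at 0.05–0.1% AF where Poisson input-copy
dropout operates) and 0–0.05 false positives per 10,000 variant tests.

## Known limitations

- Each alternative allele is tested independently; no phasing or joint
  multi-allelic model.
- The mpileup deletion token keys by length only; the deleted sequence
  is restored from a reference FASTA at VCF writing time (or `N`
  placeholders without one).
- Dispersion is a two-parameter trend plus per-variant escalation, not a
  full local regression; with >= 8 control replicates a per-variant
  estimate would beat it.
- The normal tail approximation beyond T = 10,000 is slightly
  anti-conservative in extreme tails; it only affects variants whose
  evidence is overwhelming in any case.
- The single-replicate fallback prior (alpha = 0.1) is a convention, not
  an estimate; single-replicate calls below ~0.5% AF should be treated
  as provisional.
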