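# replicall

Replicate-aware calling of ultralow-frequency SNVs and indels in deep
targeted sequencing data.

## The problem

Liquid-biopsy and other deep amplicon assays need somatic variants at
0.05–1% allele frequency (AF), a regime where library and sequencing
errors produce signals of the same size as the variants themselves.
Those errors come in two flavors: *recurrent artifacts* (error-prone
loci that light up in every library made with the same chemistry) and
*stochastic errors* (random polymerase errors that enter one library but
not its siblings, dominating below ~0.5% AF). Filters on base quality,
depth and strand bias alone stop working below ~2% AF.

`replicall` is for groups that can sequence technical replicates: N
replicates of the sample and M replicates of wild-type control DNA
(the controls need sequencing only once and are reused across samples).
For every candidate variant it asks whether the sample replicates'
supporting read counts are *statistically enriched* over the control
replicates' — recurrent artifacts are present in the controls and
cancel; stochastic errors are exposed by their inconsistency across
sample replicates.

## The statistical core

Per-replicate counts at a variant are modeled as negative binomial with
mean s_j·q (size factor × rate) and variance μ + αμ². Under the null,
sample and control share one rate; conditioning on the pooled total
T = K_A + K_B, the one-sided exact p-value is

    p = Σ_{a ≥ K_A} P_A(a) P_B(T−a)  /  Σ_{a=0..T} P_A(a) P_B(T−a),

with K_A ~ NB(mean q·S_A, var q·S_A + α·Σ_j s_j²·q²) and K_B analogous
(in the Poisson limit α = 0 this is exactly a binomial test on the
split). Size factors are median-of-ratios over per-position depths;
dispersions come from a mean–dispersion trend α(μ) = a0 + a1/μ over the
control background, escalated to the empirical estimate only where a
variant's replicate scatter — control *or sample* side — significantly
exceeds shot noise (the sample-side screen is what removes stochastic
errors). P-values are Benjamini–Hochberg adjusted across the panel's
full variant space (bp × 4: three SNVs and one indel test per base), and
calls must additionally pass a mean-AF threshold, a Strand Bias Factor
filter (fwd AF / rev AF, magnitude > 5 excluded) and the enrichment
direction check. See `docs/methods.md` for the full model.

## Worked example

Simulate a small 4+4 replicate experiment with three spikes near 1% AF,
call, and score:

```
$ replicall simulate --panel-bp 400 --n-truth 3 --af-low 0.005 \
      --af-high 0.01 --seed 7 --out-dir demo
simulated 400 bp x 4+4 replicates (3 truth variants, 16 artifact loci) -> demo

$ replicall call \
      --sample demo/sample_1.pileup --sample demo/sample_2.pileup \
      --sample demo/sample_3.pileup --sample demo/sample_4.pileup \
      --control demo/control_1.pileup --control demo/control_2.pileup \
      --control demo/control_3.pileup --control demo/control_4.pileup \
      --panel demo/panel.bed --reference demo/reference.fa --out demo/calls
3 variants called; wrote demo/calls.tsv and demo/calls.vcf

$ grep -v "^##" demo/calls.vcf
#CHROM  POS  ID  REF  ALT  QUAL  FILTER  INFO
sim1    175  .   A    C    .     PASS    AF=0.00768172;P=7.6924e-43;ADJP=1.23078e-39;SBF=0.932624;NREP_SUP=4
sim1    264  .   G    A    .     PASS    AF=0.00550262;P=7.17189e-23;ADJP=3.82501e-20;SBF=0.812624;NREP_SUP=4
sim1    324  .   T    G    .     PASS    AF=0.00989197;P=3.23795e-26;ADJP=2.59036e-23;SBF=1.11823;NREP_SUP=4

$ replicall evaluate --calls demo/calls.vcf --truth demo/truth.vcf --panel demo/panel.bed
TP=3 FP=0 FN=0 TN=1597 (of 1600 variant tests)
sensitivity = 100.0000%
specificity = 100.0000%
false positives per 10k variant tests = 0
```

All three spiked variants come back: `AF` is the mean allele frequency
across the four sample replicates (e.g. 0.0077 ≈ the 0.75% spike),
`ADJP` the BH-adjusted p-value driving the call, `SBF` the strand bias
factor (near 1 = balanced strands), and `NREP_SUP` the number of sample
replicates with supporting reads. The 16 recurrent artifact loci and the
simulation's stochastic errors produce no false calls among the 400 × 4
= 1600 variant tests.

The `matrix` subcommand dumps the intermediate variant × replicate count
matrix as TSV; `--emit-all` on `call` writes rejected candidates with
their rejection reason in the VCF FILTER column.

## What it is not

No read processing: trimming, alignment, recalibration and pileup
generation happen upstream (the tool consumes `samtools mpileup` text or
a documented TSV count format). No germline annotation, no consequence
prediction, no UMI handling.
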